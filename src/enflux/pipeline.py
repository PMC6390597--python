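"""End-to-end pipeline orchestration and summary tables.

The pipeline follows the analysis order of the study it encodes:
generate the virtual cohort → simulate 90-day trajectories → build (or
load) plausibility envelopes → stratify → run the activation experiment
on the final subgroup → summarise.  Every stage draws its randomness from
a stage-specific child of the single top-level seed, so a fixed config
reproduces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as eio
from .calorimetry import CalorimetryConstants, ee_from_gas_exchange
from .cohort import (
    DEFAULT_DIET,
    CalorimetryTargets,
    CohortHyperparams,
    generate_calorimetry_cohort,
    generate_cohort,
)
from .energy import ee_series, energy_profile, mean_ee
from .model import DietSpec, SimulationError, simulate_trajectory
from .perturb import DEFAULT_LADDER, run_ladder, select_activation
from .stratify import (
    EEConstraints,
    build_envelopes,
    stratify_cohort,
)

logger = logging.getLogger("enflux")

__all__ = ["PipelineConfig", "run_pipeline", "summary_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Flat, serialisable configuration for the whole pipeline."""

    seed: int = 1
    n_individuals: int = 200
    diet: DietSpec = DEFAULT_DIET
    hyper: CohortHyperparams = field(default_factory=CohortHyperparams)
    constants: CalorimetryConstants = field(default_factory=CalorimetryConstants)
    ee_constraints: EEConstraints = field(default_factory=EEConstraints)
    ladder: tuple[float, ...] = DEFAULT_LADDER
    min_rel_increase: float = 1e-3
    fat_threshold: float = 0.57
    envelope_coverage: float = 0.95
    n_mice: int = 8
    cage_noise_sd: float = 0.03
    ee_histogram_edges: tuple[float, ...] = tuple(float(x) for x in range(0, 32, 2))

    def __post_init__(self) -> None:
        # the cohort hyperparams inherit the top-level seed and size
        object.__setattr__(
            self,
            "hyper",
            dataclasses.replace(self.hyper, n=self.n_individuals, seed=self.seed),
        )

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [conv(v) for v in obj]
            if isinstance(obj, np.floating):
                return float(obj)
            if isinstance(obj, np.integer):
                return int(obj)
            return obj

        return {
            f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "diet" in kwargs:
            kwargs["diet"] = DietSpec(**kwargs["diet"])
        if "hyper" in kwargs:
            kwargs["hyper"] = CohortHyperparams(**kwargs["hyper"])
        if "constants" in kwargs:
            kwargs["constants"] = CalorimetryConstants(**kwargs["constants"])
        if "ee_constraints" in kwargs:
            ee = kwargs["ee_constraints"]
            ee = {k: tuple(v) if isinstance(v, list) else v for k, v in ee.items()}
            kwargs["ee_constraints"] = EEConstraints(**ee)
        for key in ("ladder", "ee_histogram_edges"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and persist its artifacts under ``outdir``.

    Returns a dict of in-memory stage results.  Any stage failure raises
    with the stage named.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    cage_seed = int(seeds[1].generate_state(1)[0] % (2**31))

    # stage 1: cohort -----------------------------------------------------
    cohort = generate_cohort(config.hyper, config.diet)
    eio.save_cohort(cohort, out / "cohort.json")
    logger.info("stage cohort: generated %d individuals", len(cohort))

    # stage 2: trajectories ----------------------------------------------
    trajectories = {}
    failed: list[str] = []
    for ind in cohort:
        try:
            trajectories[ind.id] = simulate_trajectory(ind, config.diet)
        except SimulationError as exc:  # pragma: no cover - defensive
            failed.append(ind.id)
            logger.warning("stage simulate: %s", exc)
    if not trajectories:
        raise RuntimeError("stage simulate: no trajectory could be integrated")
    ee_rows = [
        {
            "individual_id": iid,
            "mean_ee_kcal_day": mean_ee(t),
            "ee_day21": float(ee_series(t)[21]),
            "ee_day70": float(ee_series(t)[70]),
            "ee_day90": float(ee_series(t)[90]),
        }
        for iid, t in trajectories.items()
    ]
    ee_summary = pd.DataFrame(ee_rows)
    ee_summary.to_csv(out / "ee_summary.csv", index=False)
    logger.info("stage simulate: %d trajectories (%d failed)", len(trajectories), len(failed))

    # stage 3: calorimetry reference (synthetic cages) --------------------
    records = generate_calorimetry_cohort(
        n_mice=config.n_mice,
        seed=cage_seed,
        targets=CalorimetryTargets(),
        constants=config.constants,
        noise_sd=config.cage_noise_sd,
    )
    eio.save_gas_records(records, out / "gas_exchange.csv")

    # stage 4: stratification ---------------------------------------------
    envelopes = build_envelopes(trajectories, config.envelope_coverage)
    report = stratify_cohort(
        trajectories,
        envelopes,
        config.ee_constraints,
        config.fat_threshold,
    )
    eio.save_json(report.to_dict(), out / "stratification.json")
    logger.info(
        "stage stratify: %d -> biomarkers %d -> EE %d -> subgroups %s -> fat %d",
        report.n_input,
        report.n_biomarker_pass,
        report.n_ee_pass,
        report.subgroup_counts,
        report.n_fat_pass,
    )

    # stage 5: activation experiment on the final subgroup ----------------
    by_id = {ind.id: ind for ind in cohort}
    perturbations = {}
    for iid in report.final_ids:
        res = run_ladder(by_id[iid], config.diet, config.ladder)
        select_activation(res, config.min_rel_increase)
        perturbations[iid] = res
    pert_rows = []
    change_rows = []
    for iid, res in perturbations.items():
        row = {
            "individual_id": iid,
            "baseline_ee_total": res.baseline_profile.ee_total,
            "selected_factor": res.selected_factor,
            "rel_ee_increase": res.selected_rel_increase,
        }
        if res.shift is not None:
            row.update(
                delta_ee_per=res.shift.delta_ee_per,
                delta_ee_hep=res.shift.delta_ee_hep,
                delta_ee_total=res.shift.delta_ee_total,
                delta_surplus=res.shift.delta_surplus,
            )
        pert_rows.append(row)
        if res.change_map is not None:
            for var, val in res.change_map.items():
                change_rows.append(
                    {"individual_id": iid, "variable": var, "relative_change": val}
                )
    pd.DataFrame(pert_rows).to_csv(out / "perturbation_summary.csv", index=False)
    pd.DataFrame(change_rows).to_csv(out / "relative_changes.csv", index=False)
    logger.info(
        "stage perturb: %d candidates, %d selected",
        len(perturbations),
        sum(1 for r in perturbations.values() if r.selected_factor is not None),
    )

    config.to_yaml(out / "config.yaml")
    results = {
        "cohort": cohort,
        "trajectories": trajectories,
        "gas_records": records,
        "envelopes": envelopes,
        "report": report,
        "perturbations": perturbations,
        "ee_summary": ee_summary,
    }
    summary_report(results, config, out)
    return results


def summary_report(results: dict, config: PipelineConfig, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Plot-ready summary tables: calorimetry stats, EE histogram,
    peripheral-fraction spectrum and the perturbation energy shifts."""
    out = Path(outdir)
    tables: dict[str, pd.DataFrame] = {}

    # calorimetry table (population statistics of the synthetic cages)
    ox = [ee_from_gas_exchange(r, config.constants) for r in results["gas_records"]]
    cal = pd.DataFrame(
        {
            "ee_total": [o.ee_total for o in ox],
            "fat_oxidation_pct": [100 * o.energy_fractions[1] for o in ox],
            "carb_oxidation_pct": [100 * o.energy_fractions[0] for o in ox],
            "protein_oxidation_pct": [100 * o.energy_fractions[2] for o in ox],
        }
    )
    tables["calorimetry_stats"] = cal.agg(["mean", "std"]).T.reset_index(names="quantity")

    # EE histogram over the whole simulated cohort
    edges = np.asarray(config.ee_histogram_edges)
    counts, _ = np.histogram(results["ee_summary"]["mean_ee_kcal_day"], bins=edges)
    tables["ee_histogram"] = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )

    # peripheral/hepatic spectrum at the three-month time point (EE-passing set)
    report = results["report"]
    spec_rows = []
    for iid, flag in report.flags.items():
        if flag.get("ee_pass"):
            profile = energy_profile(results["trajectories"][iid])
            spec_rows.append(
                {
                    "individual_id": iid,
                    "peripheral_fraction": profile.peripheral_fraction,
                    "hepatic_fraction": 1.0 - profile.peripheral_fraction,
                    "subgroup": flag.get("subgroup"),
                    "per_carb_frac": profile.substrates_per[0],
                    "per_fat_frac": profile.substrates_per[1],
                    "per_protein_frac": profile.substrates_per[2],
                    "hep_carb_frac": profile.substrates_hep[0],
                    "hep_fat_frac": profile.substrates_hep[1],
                    "hep_protein_frac": profile.substrates_hep[2],
                }
            )
    spectrum = pd.DataFrame(spec_rows)
    if not spectrum.empty:
        spectrum = spectrum.sort_values("peripheral_fraction", ascending=False)
    tables["peripheral_spectrum"] = spectrum

    # perturbation overview (may be empty when the final subgroup is empty)
    pert = results["perturbations"]
    n_sel = sum(1 for r in pert.values() if r.selected_factor is not None)
    tables["perturbation_overview"] = pd.DataFrame(
        [
            {
                "n_final_subgroup": len(pert),
                "n_selected": n_sel,
                "mean_delta_ee_total": float(
                    np.mean([r.shift.delta_ee_total for r in pert.values() if r.shift])
                )
                if n_sel
                else np.nan,
                "mean_delta_surplus": float(
                    np.mean([r.shift.delta_surplus for r in pert.values() if r.shift])
                )
                if n_sel
                else np.nan,
            }
        ]
    )

    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    return tables
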