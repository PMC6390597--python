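"""Virtual-cohort stratification.

The pipeline reduces a raw cohort of virtual individuals to the
physiologically admissible, predominantly-peripheral, fat-burning subset
in four stages, in this order:

1. **Plausibility** — pools stay inside per-variable envelopes and fluxes
   below caps (a stand-in for agreement with the original calibration
   data; the default envelopes are the central 95% band of the synthetic
   cohort itself).
2. **Energy expenditure** — the EE trajectory satisfies all four
   indirect-calorimetry criteria: EE at three weeks (day 21) inside the
   3-week 99.7% CI, EE at ten weeks (day 70) inside the 10-week CI,
   overall minimum above the 3-week lower bound, overall maximum below
   20 kcal/day.
3. **Subgroup** — individuals are classified by the peripheral fraction of
   EE at the three-month time point: [P] (> 80% peripheral), [H] (> 80%
   hepatic), [P+H] (both compartments contribute > 20%).  The analysis
   retains subgroup [P].
4. **Substrate oxidation** — at least 57% of the (peripheral) energy must
   originate from lipid substrates.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .energy import ee_series, energy_profile
from .model import Trajectory

__all__ = [
    "EEConstraints",
    "SubgroupLabel",
    "Envelopes",
    "StratificationReport",
    "build_envelopes",
    "filter_plausibility",
    "filter_ee",
    "classify_subgroup",
    "filter_fat_oxidation",
    "stratify_cohort",
]

DAY_3W = 21
DAY_10W = 70
FAT_OXIDATION_THRESHOLD = 0.57


class SubgroupLabel(str, Enum):
    P = "P"       # predominantly peripheral EE (> 80%)
    H = "H"       # predominantly hepatic EE (> 80%)
    PH = "PH"     # both compartments contribute > 20%


@dataclass(frozen=True)
class EEConstraints:
    """Physiological EE window (kcal/day) from the indirect-calorimetry CIs."""

    ci_3w: tuple[float, float] = (8.4, 13.7)
    ci_10w: tuple[float, float] = (9.5, 15.7)
    overall_min: float = 8.4
    overall_max: float = 20.0


#: pools acting as plasma/liver biomarkers (glycemia, triglyceridemia,
#: hepatic steatosis); the energy stores themselves are judged by the EE
#: stage, not here
BIOMARKER_POOLS = ("glc_plasma", "tg_plasma", "tg_hep")
#: transport fluxes subject to the "unrealistic flux magnitude" caps
CAPPED_FLUXES = (
    "uptake_glc_hep",
    "uptake_glc_per",
    "uptake_tg_hep",
    "uptake_tg_per",
    "vldl_secretion",
)


@dataclass(frozen=True)
class Envelopes:
    """Admissible per-variable bands for pools and caps for fluxes.

    Only the variables named in the two mappings are checked; an envelope
    naming a variable the trajectory does not carry is a configuration
    error.
    """

    pool_bounds: dict[str, tuple[float, float]]
    flux_caps: dict[str, float]


@dataclass
class StratificationReport:
    n_input: int
    n_biomarker_pass: int
    n_ee_pass: int
    subgroup_counts: dict[str, int]
    n_fat_pass: int
    final_ids: list[str]
    flags: dict[str, dict] = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_biomarker_pass": self.n_biomarker_pass,
            "n_ee_pass": self.n_ee_pass,
            "subgroup_counts": dict(self.subgroup_counts),
            "n_fat_pass": self.n_fat_pass,
            "final_ids": list(self.final_ids),
            "flags": self.flags,
        }


def build_envelopes(
    trajectories: dict[str, Trajectory],
    coverage: float = 0.95,
    pool_vars: tuple[str, ...] = BIOMARKER_POOLS,
    flux_vars: tuple[str, ...] = CAPPED_FLUXES,
) -> Envelopes:
    """Envelopes from a reference cohort: central ``coverage`` band.

    Pool bounds are the (1−coverage)/2 and 1−(1−coverage)/2 quantiles of
    the per-individual extrema of the biomarker pools; flux caps are the
    upper quantile of the per-individual transport-flux maxima.
    """
    if not trajectories:
        raise ValueError("cannot build envelopes from an empty cohort")
    q = (1.0 - coverage) / 2.0
    mins = pd.DataFrame({i: t.pools.min() for i, t in trajectories.items()}).T
    maxs = pd.DataFrame({i: t.pools.max() for i, t in trajectories.items()}).T
    fmax = pd.DataFrame({i: t.fluxes.max() for i, t in trajectories.items()}).T
    pool_bounds = {
        v: (float(mins[v].quantile(q)), float(maxs[v].quantile(1.0 - q)))
        for v in pool_vars
    }
    flux_caps = {v: float(fmax[v].quantile(1.0 - q)) for v in flux_vars}
    return Envelopes(pool_bounds=pool_bounds, flux_caps=flux_caps)


def filter_plausibility(
    trajectory: Trajectory, envelopes: Envelopes
) -> tuple[bool, list[str]]:
    """True iff every enveloped pool stays inside its band and every capped
    flux stays below its cap."""
    reasons: list[str] = []
    for v, (lo, hi) in envelopes.pool_bounds.items():
        if v not in trajectory.pools.columns:
            raise KeyError(f"envelope names unknown pool variable {v!r}")
        col = trajectory.pools[v]
        if col.min() < lo:
            reasons.append(f"pool {v} below envelope ({col.min():.3g} < {lo:.3g})")
        if col.max() > hi:
            reasons.append(f"pool {v} above envelope ({col.max():.3g} > {hi:.3g})")
    for v, cap in envelopes.flux_caps.items():
        if v not in trajectory.fluxes.columns:
            raise KeyError(f"envelope names unknown flux variable {v!r}")
        mx = trajectory.fluxes[v].max()
        if mx > cap:
            reasons.append(f"flux {v} above cap ({mx:.3g} > {cap:.3g})")
    return (len(reasons) == 0, reasons)


def filter_ee(
    ee: np.ndarray,
    constraints: EEConstraints = EEConstraints(),
    time: np.ndarray | None = None,
) -> tuple[bool, list[str]]:
    """Apply the four EE admissibility criteria to an EE trajectory.

    ``ee`` must be defined on the daily 0..90 grid (or supply ``time``);
    the 3-week and 10-week checks are evaluated at days 21 and 70.
    """
    ee = np.asarray(ee, dtype=float)
    if time is None:
        time = np.arange(len(ee), dtype=float)
    idx3 = np.nonzero(np.isclose(time, DAY_3W))[0]
    idx10 = np.nonzero(np.isclose(time, DAY_10W))[0]
    if idx3.size == 0 or idx10.size == 0:
        raise ValueError("EE grid must contain days 21 and 70")
    reasons: list[str] = []
    e3, e10 = ee[idx3[0]], ee[idx10[0]]
    if not (constraints.ci_3w[0] <= e3 <= constraints.ci_3w[1]):
        reasons.append(f"ee_3w {e3:.2f} outside {constraints.ci_3w}")
    if not (constraints.ci_10w[0] <= e10 <= constraints.ci_10w[1]):
        reasons.append(f"ee_10w {e10:.2f} outside {constraints.ci_10w}")
    if ee.min() < constraints.overall_min:
        reasons.append(f"overall_min {ee.min():.2f} < {constraints.overall_min}")
    if ee.max() >= constraints.overall_max:
        reasons.append(f"overall_max {ee.max():.2f} >= {constraints.overall_max}")
    return (len(reasons) == 0, reasons)


def classify_subgroup(peripheral_fraction: float) -> SubgroupLabel:
    """[P] if > 80% peripheral, [H] if > 80% hepatic, else [P+H].

    The boundary values (exactly 80%/20%) fall into the intermediate
    group because the defining inequalities are strict.
    """
    if not 0.0 <= peripheral_fraction <= 1.0:
        raise ValueError("peripheral fraction must lie in [0, 1]")
    if peripheral_fraction > 0.80:
        return SubgroupLabel.P
    if peripheral_fraction < 0.20:
        return SubgroupLabel.H
    return SubgroupLabel.PH


def filter_fat_oxidation(
    substrate_fractions: tuple[float, float, float],
    threshold: float = FAT_OXIDATION_THRESHOLD,
) -> bool:
    """True iff at least ``threshold`` of energy originates from lipids.

    ``substrate_fractions`` is the (carb, fat, protein) energy split of
    the dominant compartment.
    """
    if abs(sum(substrate_fractions) - 1.0) > 1e-6:
        raise ValueError("substrate fractions must sum to 1")
    return substrate_fractions[1] >= threshold


def stratify_cohort(
    trajectories: dict[str, Trajectory],
    envelopes: Envelopes,
    constraints: EEConstraints = EEConstraints(),
    fat_threshold: float = FAT_OXIDATION_THRESHOLD,
    shuffle_seed: int | None = None,
) -> StratificationReport:
    """Run the four-stage stratification over a simulated cohort.

    Returns per-stage survivor counts, per-individual flags with rejection
    reasons, and the final id list (subgroup [P] passing the fat-oxidation
    criterion).  The result is independent of cohort ordering; a
    ``shuffle_seed`` can be supplied to randomise iteration order when
    exercising that property.
    """
    if not trajectories:
        raise ValueError("cohort is empty")
    ids = list(trajectories)
    if shuffle_seed is not None:
        random.Random(shuffle_seed).shuffle(ids)

    flags: dict[str, dict] = {}
    n_bio = 0
    n_ee = 0
    subgroup_counts = {label.value: 0 for label in SubgroupLabel}
    n_fat = 0
    final_ids: list[str] = []

    for iid in ids:
        traj = trajectories[iid]
        entry: dict = {"id": iid}
        flags[iid] = entry

        ok_bio, reasons = filter_plausibility(traj, envelopes)
        entry["biomarker_pass"] = ok_bio
        entry["biomarker_reasons"] = reasons
        if not ok_bio:
            continue
        n_bio += 1

        ok_ee, reasons = filter_ee(ee_series(traj), constraints, time=traj.time)
        entry["ee_pass"] = ok_ee
        entry["ee_reasons"] = reasons
        if not ok_ee:
            continue
        n_ee += 1

        profile = energy_profile(traj)  # three-month time point
        label = classify_subgroup(profile.peripheral_fraction)
        entry["subgroup"] = label.value
        entry["peripheral_fraction"] = profile.peripheral_fraction
        subgroup_counts[label.value] += 1
        if label is not SubgroupLabel.P:
            continue

        ok_fat = filter_fat_oxidation(profile.substrates_per, fat_threshold)
        entry["fat_pass"] = ok_fat
        entry["fat_energy_fraction"] = profile.substrates_per[1]
        if ok_fat:
            n_fat += 1
            final_ids.append(iid)

    final_ids.sort()
    return StratificationReport(
        n_input=len(ids),
        n_biomarker_pass=n_bio,
        n_ee_pass=n_ee,
        subgroup_counts=subgroup_counts,
        n_fat_pass=n_fat,
        final_ids=final_ids,
        flags=flags,
    )
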