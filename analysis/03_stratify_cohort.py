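#!/usr/bin/env python
"""Stratify the simulated cohort into the admissible [P] fat-burning subset.

Re-simulates the seeded default cohort, applies the four-stage filter
chain (biomarker plausibility → EE window → subgroup → fat oxidation)
and writes the stage counts, the peripheral/hepatic spectrum, and the
cohort energy balance of the EE-admissible individuals.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from enflux.cohort import DEFAULT_DIET, CohortHyperparams, generate_cohort
from enflux.energy import ee_series, energy_balance, energy_profile, mean_ee
from enflux.model import simulate_trajectory
from enflux.stratify import build_envelopes, filter_ee, stratify_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = generate_cohort(CohortHyperparams())
    trajectories = {c.id: simulate_trajectory(c, DEFAULT_DIET) for c in cohort}
    envelopes = build_envelopes(trajectories)
    report = stratify_cohort(trajectories, envelopes)

    counts = pd.DataFrame(
        [
            {"stage": "input", "n": report.n_input},
            {"stage": "biomarker_plausibility", "n": report.n_biomarker_pass},
            {"stage": "ee_window", "n": report.n_ee_pass},
            {"stage": "subgroup_P", "n": report.subgroup_counts["P"]},
            {"stage": "subgroup_H", "n": report.subgroup_counts["H"]},
            {"stage": "subgroup_PH", "n": report.subgroup_counts["PH"]},
            {"stage": "fat_oxidation_ge_57pct", "n": report.n_fat_pass},
        ]
    )
    (ROOT / "results").mkdir(exist_ok=True)
    counts.to_csv(ROOT / "results" / "stratification_counts.csv", index=False)

    rows = []
    for iid, flag in report.flags.items():
        if not flag.get("ee_pass"):
            continue
        p = energy_profile(trajectories[iid])
        rows.append(
            {
                "individual_id": iid,
                "peripheral_fraction": p.peripheral_fraction,
                "subgroup": flag["subgroup"],
                "per_carb_frac": p.substrates_per[0],
                "per_fat_frac": p.substrates_per[1],
                "per_protein_frac": p.substrates_per[2],
            }
        )
    spectrum = pd.DataFrame(rows).sort_values("peripheral_fraction", ascending=False)
    spectrum.to_csv(ROOT / "results" / "peripheral_spectrum.csv", index=False)

    surpluses = [
        energy_balance(DEFAULT_DIET.energy_intake, mean_ee(t)).surplus
        for t in trajectories.values()
        if filter_ee(ee_series(t), time=t.time)[0]
    ]
    pd.DataFrame(
        [{"n_ee_pass": len(surpluses), "intake_kcal_day": DEFAULT_DIET.energy_intake,
          "mean_surplus_kcal_day": np.mean(surpluses)}]
    ).to_csv(ROOT / "results" / "energy_balance.csv", index=False)

    print("stratification chain:", " → ".join(f"{r.stage}={r.n}" for r in counts.itertuples()))
    print(
        f"peripheral fraction spans {spectrum.peripheral_fraction.min():.2f}–"
        f"{spectrum.peripheral_fraction.max():.2f} (continuous spectrum, all three subgroups present)"
    )
    print(
        f"EE-admissible cohort (n={len(surpluses)}): mean surplus "
        f"{np.mean(surpluses):.2f} kcal/day at {DEFAULT_DIET.energy_intake:.0f} kcal/day intake"
    )
    print("wrote results/stratification_counts.csv, peripheral_spectrum.csv, energy_balance.csv")


if __name__ == "__main__":
    main()
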