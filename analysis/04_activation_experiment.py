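#!/usr/bin/env python
"""In-silico activation of peripheral energy expenditure on the final subgroup.

For every individual that survived stratification, sweeps the activation
ladder (1+1e-10 … 25) on the peripheral ACoA respiration flux with diet
held fixed, selects the factor with the highest total-EE gain (if at
least 0.1%), and summarises the energy shifts and the relative changes
of pools and fluxes across the subgroup.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from enflux.cohort import DEFAULT_DIET, CohortHyperparams, generate_cohort
from enflux.model import simulate_trajectory
from enflux.perturb import run_ladder, select_activation
from enflux.stratify import build_envelopes, stratify_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = generate_cohort(CohortHyperparams())
    trajectories = {c.id: simulate_trajectory(c, DEFAULT_DIET) for c in cohort}
    report = stratify_cohort(trajectories, build_envelopes(trajectories))
    by_id = {c.id: c for c in cohort}

    rows, change_maps = [], {}
    for iid in report.final_ids:
        res = run_ladder(by_id[iid], DEFAULT_DIET)
        select_activation(res)
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
            change_maps[iid] = res.change_map
        rows.append(row)
    summary = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    summary.to_csv(ROOT / "results" / "perturbation_summary.csv", index=False)

    cm = pd.DataFrame(change_maps)  # variables × individuals
    agg = pd.DataFrame(
        {
            "median_rel_change": cm.median(axis=1),
            "min_rel_change": cm.min(axis=1),
            "max_rel_change": cm.max(axis=1),
            "n_decreasing": (cm < 0).sum(axis=1),
            "n_increasing": (cm > 0).sum(axis=1),
        }
    )
    agg.index.name = "variable"
    agg.to_csv(ROOT / "results" / "relative_change_summary.csv")

    sel = summary.dropna(subset=["selected_factor"])
    print(f"final subgroup n={len(summary)}, activation selected in n={len(sel)}")
    print(
        f"total-EE gain at selection: {100 * sel.rel_ee_increase.min():.2f}%–"
        f"{100 * sel.rel_ee_increase.max():.2f}% (median {100 * sel.rel_ee_increase.median():.2f}%)"
    )
    print(
        f"energy surplus shrinks by {-sel.delta_surplus.max():.2f}–"
        f"{-sel.delta_surplus.min():.2f} kcal/day; peripheral EE rises, hepatic EE falls "
        f"(median Δee_per {sel.delta_ee_per.median():+.2f}, Δee_hep {sel.delta_ee_hep.median():+.2f} kcal/day)"
    )
    print(
        "peripheral TG and plasma lipoprotein TG decrease in "
        f"{int(agg.loc['tg_per', 'n_decreasing'])}/{len(sel)} and "
        f"{int(agg.loc['tg_plasma', 'n_decreasing'])}/{len(sel)} selected individuals; "
        f"carbohydrate pools change by at most {cm.loc[['glc_plasma', 'g6p_hep', 'g6p_per']].abs().max().max():.1e}"
    )
    print("wrote results/perturbation_summary.csv and results/relative_change_summary.csv")


if __name__ == "__main__":
    main()
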