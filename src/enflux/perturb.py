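"""In-silico activation of peripheral energy expenditure.

The experiment emulates brown-adipose-tissue-like activation: the
peripheral ACoA respiration flux is multiplied by an activation factor
f_act spanning several scales, from 1 + 10⁻¹⁰ up to 25.  For each factor
the system is re-solved to steady state with dietary intake held fixed at
its original values, starting from the individual's fully developed
(day-90) baseline state.  The factor achieving the highest increase in
total EE — provided it yields at least a 0.1% relative increase — is
selected for further analysis; factors that drain the peripheral ACoA
pool below the depletion floor are infeasible and flagged, not fatal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEPLETION_FLOOR
from .energy import EnergyProfile, energy_profile
from .model import DietSpec, SteadyState, VirtualIndividual, compute_steady_state

__all__ = [
    "DEFAULT_LADDER",
    "default_ladder",
    "FactorResult",
    "PerturbationResult",
    "EnergyShift",
    "ExperimentError",
    "run_ladder",
    "select_activation",
    "energy_shift",
    "relative_changes",
]

MIN_REL_INCREASE = 1e-3


def default_ladder() -> tuple[float, ...]:
    """The activation-factor ladder:
    1+1e-10, 1+1e-8, 1+1e-6, 1+1e-4, 1+1e-3, 1+1e-2, 1.1:0.1:1.9, 2:9, 10:5:25.
    """
    small = [1 + 1e-10, 1 + 1e-8, 1 + 1e-6, 1 + 1e-4, 1 + 1e-3, 1 + 1e-2]
    tenths = [round(1.0 + 0.1 * k, 10) for k in range(1, 10)]
    units = [float(k) for k in range(2, 10)]
    coarse = [10.0, 15.0, 20.0, 25.0]
    return tuple(small + tenths + units + coarse)


DEFAULT_LADDER: tuple[float, ...] = default_ladder()


class ExperimentError(RuntimeError):
    """Raised when the baseline steady state of an individual is unusable."""


@dataclass
class FactorResult:
    factor: float
    steady_state: SteadyState
    profile: EnergyProfile | None     # None when infeasible
    feasible: bool


@dataclass
class EnergyShift:
    """Change in EE decomposition at fixed dietary intake."""

    delta_ee_per: float
    delta_ee_hep: float
    delta_ee_total: float
    delta_surplus: float              # = −delta_ee_total at fixed intake


@dataclass
class PerturbationResult:
    individual_id: str
    baseline: SteadyState
    baseline_profile: EnergyProfile
    factors: list[FactorResult] = field(repr=False)
    selected_factor: float | None = None
    selected_rel_increase: float | None = None
    shift: EnergyShift | None = None
    change_map: pd.Series | None = None


def run_ladder(
    individual: VirtualIndividual,
    diet: DietSpec,
    ladder: tuple[float, ...] = DEFAULT_LADDER,
    baseline: SteadyState | None = None,
) -> PerturbationResult:
    """Re-solve the steady state for every rung of the activation ladder.

    The baseline (f_act = 1) steady state is computed first (or taken from
    the caller) and used as the initial guess for every perturbed solve —
    dietary intake is never changed.
    """
    if baseline is None:
        baseline = compute_steady_state(individual, diet, f_act=1.0)
    if not baseline.converged:
        raise ExperimentError(
            f"baseline steady state did not converge for {individual.id!r}"
        )
    base_profile = energy_profile(baseline)
    x0 = baseline.pools.to_numpy()

    results: list[FactorResult] = []
    for factor in ladder:
        ss = compute_steady_state(individual, diet, f_act=factor, x0=x0)
        profile = energy_profile(ss) if ss.converged else None
        results.append(
            FactorResult(
                factor=factor, steady_state=ss, profile=profile, feasible=ss.converged
            )
        )
    return PerturbationResult(
        individual_id=individual.id,
        baseline=baseline,
        baseline_profile=base_profile,
        factors=results,
    )


def select_activation(
    result: PerturbationResult,
    min_rel_increase: float = MIN_REL_INCREASE,
    tie_tol: float = 1e-9,
) -> float | None:
    """Pick the feasible factor with the highest total-EE increase.

    Returns ``None`` when no feasible factor improves total EE by at least
    ``min_rel_increase`` of baseline.  Factors whose EE agrees with the
    maximum within ``tie_tol`` (relative) tie-break to the smallest such
    factor, for stability.  The selection and the implied energy shift and
    relative-change map are stored on ``result`` and the factor returned.
    """
    base_ee = result.baseline_profile.ee_total
    feasible = [fr for fr in result.factors if fr.feasible and fr.profile is not None]
    if not feasible:
        result.selected_factor = None
        return None
    best_ee = max(fr.profile.ee_total for fr in feasible)
    rel = (best_ee - base_ee) / base_ee
    if rel < min_rel_increase:
        result.selected_factor = None
        result.selected_rel_increase = rel
        return None
    for fr in sorted(feasible, key=lambda r: r.factor):
        if fr.profile.ee_total >= best_ee * (1.0 - tie_tol):
            chosen = fr
            break
    result.selected_factor = chosen.factor
    result.selected_rel_increase = (chosen.profile.ee_total - base_ee) / base_ee
    result.shift = energy_shift(result.baseline_profile, chosen.profile)
    if result.baseline is not None and chosen.steady_state is not None:
        result.change_map = relative_changes(result.baseline, chosen.steady_state)
    return chosen.factor


def energy_shift(baseline: EnergyProfile, perturbed: EnergyProfile) -> EnergyShift:
    """EE shifts between two profiles; Δsurplus = −ΔEE_total at fixed intake."""
    d_per = perturbed.ee_per - baseline.ee_per
    d_hep = perturbed.ee_hep - baseline.ee_hep
    d_tot = perturbed.ee_total - baseline.ee_total
    return EnergyShift(
        delta_ee_per=d_per,
        delta_ee_hep=d_hep,
        delta_ee_total=d_tot,
        delta_surplus=-d_tot,
    )


def relative_changes(
    baseline: SteadyState,
    perturbed: SteadyState,
    floor: float = DEPLETION_FLOOR,
) -> pd.Series:
    """Elementwise (perturbed − baseline)/baseline over pools and fluxes.

    Variables whose baseline value sits below the depletion floor are
    reported as NaN (undefined); −1 means full depletion of the variable.
    """
    base = pd.concat([baseline.pools, baseline.fluxes])
    pert = pd.concat([perturbed.pools, perturbed.fluxes])
    if not base.index.equals(pert.index):
        raise ValueError("baseline and perturbed states expose different variables")
    out = (pert - base) / base
    out[base.abs() < floor] = np.nan
    return out
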