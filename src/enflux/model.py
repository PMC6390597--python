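"""Reduced whole-body metabolic ODE model.

Four compartments — intestinal inflow (dietary boundary fluxes), plasma,
liver and periphery — exchange carbon through mass-action kinetics.  The
state tracks eight pools (all in μmol):

* plasma glucose and plasma lipoprotein TG,
* glucose-6-phosphate (G6P), acetyl-CoA (ACoA) and triglyceride (TG) in
  liver and periphery.

Carbohydrate enters plasma glucose, is taken up into tissue G6P and feeds
ACoA via glycolysis.  Fat enters plasma TG, is taken up into tissue TG
stores and feeds ACoA via β-oxidation (1 TG → 21.4 ACoA).  The ketogenic
fraction of dietary protein is delivered directly into the tissue ACoA
pools.  Hepatic ACoA additionally drives de novo lipogenesis (DNL,
21.4 ACoA → 1 TG) and the liver secretes TG into plasma lipoproteins.
ACoA respiration in liver and periphery is the model's energy expenditure;
the peripheral respiration flux carries the activation hook

    j_resp_per = k_resp_per * ACoA_per * f_act

used by the in-silico activation experiment.

Two departures from plain mass action give the model its physiology:

1. β-oxidation (both tissues) and peripheral lipid uptake are inhibited by
   the local ACoA pool through a factor Km/(Km + ACoA).  This encodes
   energy-state feedback (acetyl-CoA/malonyl-CoA inhibition of fatty-acid
   oxidation): when respiration drains ACoA, fat mobilisation speeds up.
   Without it, steady-state respiration would be fixed by dietary inflow
   and the activation factor could not change energy expenditure at all.
2. Tissue TG pools have a first-order non-respiratory turnover (structural
   lipid incorporation/loss).  This is the sink that respiration competes
   with, so total steady-state energy expenditure genuinely rises when the
   periphery is activated, and the energy surplus shrinks without ever
   becoming a deficit.

The carbohydrate route is strictly one-way (G6P can only be donated to
ACoA) and carries no feedback, so perturbations of peripheral respiration
leave the glucose system untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .constants import (
    ACOA_PER_TG,
    DEPLETION_FLOOR,
    KCAL_PER_UMOL_AA,
    KCAL_PER_UMOL_GLUCOSE,
    KCAL_PER_UMOL_TG,
    PLASMA_VOLUME_ML,
)

__all__ = [
    "STATE_NAMES",
    "FLUX_NAMES",
    "DietSpec",
    "MetabolitePools",
    "VirtualIndividual",
    "Trajectory",
    "SteadyState",
    "SimulationError",
    "build_odes",
    "compute_fluxes",
    "simulate_trajectory",
    "compute_steady_state",
    "carbon_balance_audit",
]

#: state ordering used by every array interface; all entries in μmol
STATE_NAMES = (
    "glc_plasma",
    "tg_plasma",
    "g6p_hep",
    "acoa_hep",
    "tg_hep",
    "g6p_per",
    "acoa_per",
    "tg_per",
)

#: flux ordering; μmol/day.  β-oxidation and VLDL secretion are expressed in
#: μmol TG/day, DNL and respiration in μmol ACoA/day, everything else in
#: μmol of the transported species per day.
FLUX_NAMES = (
    "diet_carb",
    "diet_fat",
    "diet_protein_hep",
    "diet_protein_per",
    "uptake_glc_hep",
    "uptake_glc_per",
    "uptake_tg_hep",
    "uptake_tg_per",
    "glycolysis_hep",
    "glycolysis_per",
    "betaox_hep",
    "betaox_per",
    "dnl",
    "vldl_secretion",
    "resp_hep",
    "resp_per",
    "tg_loss_hep",
    "tg_loss_per",
)

#: carbon weight of each pool in ACoA equivalents (1 glucose ≡ 1 G6P ≡ 1
#: ACoA equivalent in the reduced scheme; 1 TG ≡ 21.4)
POOL_ACOA_EQUIV = {
    "glc_plasma": 1.0,
    "tg_plasma": ACOA_PER_TG,
    "g6p_hep": 1.0,
    "acoa_hep": 1.0,
    "tg_hep": ACOA_PER_TG,
    "g6p_per": 1.0,
    "acoa_per": 1.0,
    "tg_per": ACOA_PER_TG,
}


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails for an individual."""


@dataclass(frozen=True)
class DietSpec:
    """Constant dietary inflow.

    Parameters
    ----------
    carb_intake : float
        μmol glucose equivalents per day.
    fat_intake : float
        μmol TG per day.
    protein_intake : float
        μmol amino-acid equivalents per day.
    ketogenic_fraction : float
        Fraction of dietary protein routed into the ACoA pools; the
        remainder is assumed to replace structural protein and never
        enters the modelled carbon balance.
    """

    carb_intake: float
    fat_intake: float
    protein_intake: float
    ketogenic_fraction: float = 0.5

    def __post_init__(self) -> None:
        if min(self.carb_intake, self.fat_intake, self.protein_intake) < 0:
            raise ValueError("dietary intakes must be nonnegative")
        if not 0.0 <= self.ketogenic_fraction <= 1.0:
            raise ValueError("ketogenic_fraction must lie in [0, 1]")

    @property
    def energy_intake(self) -> float:
        """Total dietary energy [kcal/day], macronutrient-weighted."""
        return (
            self.carb_intake * KCAL_PER_UMOL_GLUCOSE
            + self.fat_intake * KCAL_PER_UMOL_TG
            + self.protein_intake * KCAL_PER_UMOL_AA
        )

    @classmethod
    def from_energy(
        cls,
        energy_kcal_per_day: float,
        fat_energy_fraction: float,
        carb_energy_fraction: float,
        protein_energy_fraction: float,
        ketogenic_fraction: float = 0.5,
    ) -> "DietSpec":
        """Build a diet from a caloric total and macronutrient energy split."""
        total = fat_energy_fraction + carb_energy_fraction + protein_energy_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError("macronutrient energy fractions must sum to 1")
        return cls(
            carb_intake=energy_kcal_per_day * carb_energy_fraction / KCAL_PER_UMOL_GLUCOSE,
            fat_intake=energy_kcal_per_day * fat_energy_fraction / KCAL_PER_UMOL_TG,
            protein_intake=energy_kcal_per_day * protein_energy_fraction / KCAL_PER_UMOL_AA,
            ketogenic_fraction=ketogenic_fraction,
        )


@dataclass(frozen=True)
class MetabolitePools:
    """A snapshot of the eight metabolite pools, all in μmol.

    Plasma species can be read as concentrations (mM) via
    :attr:`glc_plasma_mM` / :attr:`tg_plasma_mM` using the nominal plasma
    volume.
    """

    glc_plasma: float
    tg_plasma: float
    g6p_hep: float
    acoa_hep: float
    tg_hep: float
    g6p_per: float
    acoa_per: float
    tg_per: float
    plasma_volume_ml: float = PLASMA_VOLUME_ML

    def __post_init__(self) -> None:
        if min(self.as_array()) < 0:
            raise ValueError("metabolite pools must be nonnegative")
        if self.plasma_volume_ml <= 0:
            raise ValueError("plasma volume must be positive")

    @property
    def glc_plasma_mM(self) -> float:
        return self.glc_plasma / self.plasma_volume_ml

    @property
    def tg_plasma_mM(self) -> float:
        return self.tg_plasma / self.plasma_volume_ml

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray, plasma_volume_ml: float = PLASMA_VOLUME_ML) -> "MetabolitePools":
        vals = {n: float(v) for n, v in zip(STATE_NAMES, x)}
        return cls(plasma_volume_ml=plasma_volume_ml, **vals)


_RATE_FIELDS = (
    "k_glyc_hep",
    "k_glyc_per",
    "k_boxid_hep",
    "k_boxid_per",
    "k_resp_hep",
    "k_resp_per",
    "k_dnl",
    "k_uptake_glc_hep",
    "k_uptake_glc_per",
    "k_uptake_tg_hep",
    "k_uptake_tg_per",
    "k_secr_vldl",
    "k_loss_hep",
    "k_loss_per",
)


@dataclass(frozen=True)
class VirtualIndividual:
    """One parameterisation of the metabolic model — a virtual patient.

    All rate constants are first-order [1/day].  ``km_acoa_hep`` /
    ``km_acoa_per`` [μmol] are the half-inhibition constants of the
    energy-state feedback on fat handling; ``protein_split_hep_per`` is the
    fraction of dietary ketogenic ACoA delivered to the liver (the rest
    goes to the periphery).
    """

    id: str
    k_glyc_hep: float
    k_glyc_per: float
    k_boxid_hep: float
    k_boxid_per: float
    k_resp_hep: float
    k_resp_per: float
    k_dnl: float
    k_uptake_glc_hep: float
    k_uptake_glc_per: float
    k_uptake_tg_hep: float
    k_uptake_tg_per: float
    k_secr_vldl: float
    k_loss_hep: float
    k_loss_per: float
    km_acoa_hep: float
    km_acoa_per: float
    protein_split_hep_per: float
    initial_state: MetabolitePools = field(repr=False)

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be nonnegative")
        if self.k_resp_per <= 0:
            raise ValueError("k_resp_per must be strictly positive (activation hook)")
        if not 0.0 <= self.protein_split_hep_per <= 1.0:
            raise ValueError("protein_split_hep_per must lie in [0, 1]")
        if self.km_acoa_hep <= 0 or self.km_acoa_per <= 0:
            raise ValueError("ACoA inhibition constants must be positive")


@dataclass
class Trajectory:
    """Pools and fluxes of one individual on the daily 0..90 grid."""

    individual_id: str
    time: np.ndarray                 # (91,) days
    pools: pd.DataFrame              # (91, 8) columns = STATE_NAMES, μmol
    fluxes: pd.DataFrame             # (91, 18) columns = FLUX_NAMES, μmol/day

    def __post_init__(self) -> None:
        if len(self.time) != len(self.pools) or len(self.time) != len(self.fluxes):
            raise ValueError("time, pools and fluxes must share their grid")

    def flux_record(self, day: float) -> pd.Series:
        """Fluxes at a grid day (exact match required)."""
        idx = np.nonzero(np.isclose(self.time, day))[0]
        if idx.size == 0:
            raise KeyError(f"day {day} not on the trajectory grid")
        return self.fluxes.iloc[idx[0]]


@dataclass
class SteadyState:
    """A (possibly infeasible) steady state of the model."""

    pools: pd.Series                 # index STATE_NAMES, μmol
    fluxes: pd.Series                # index FLUX_NAMES, μmol/day
    converged: bool
    residual: float                  # max_i |dx_i/dt| / max(x_i, 1 μmol)


def compute_fluxes(
    x: np.ndarray,
    individual: VirtualIndividual,
    diet: DietSpec,
    f_act: float = 1.0,
) -> np.ndarray:
    """Evaluate all model fluxes at state ``x`` (μmol), in FLUX_NAMES order."""
    ind = individual
    s = np.maximum(np.asarray(x, dtype=float), 0.0)  # guard integrator undershoot
    glc_p, tg_p, g6p_h, acoa_h, tg_h, g6p_pe, acoa_pe, tg_pe = s

    keto = diet.ketogenic_fraction * diet.protein_intake
    phi_h = ind.km_acoa_hep / (ind.km_acoa_hep + acoa_h)
    phi_p = ind.km_acoa_per / (ind.km_acoa_per + acoa_pe)

    return np.array(
        [
            diet.carb_intake,
            diet.fat_intake,
            keto * ind.protein_split_hep_per,
            keto * (1.0 - ind.protein_split_hep_per),
            ind.k_uptake_glc_hep * glc_p,
            ind.k_uptake_glc_per * glc_p,
            ind.k_uptake_tg_hep * tg_p,
            ind.k_uptake_tg_per * tg_p * phi_p,
            ind.k_glyc_hep * g6p_h,
            ind.k_glyc_per * g6p_pe,
            ind.k_boxid_hep * tg_h * phi_h,
            ind.k_boxid_per * tg_pe * phi_p,
            ind.k_dnl * acoa_h,
            ind.k_secr_vldl * tg_h,
            ind.k_resp_hep * acoa_h,
            ind.k_resp_per * acoa_pe * f_act,
            ind.k_loss_hep * tg_h,
            ind.k_loss_per * tg_pe,
        ]
    )


def _rhs_from_fluxes(j: np.ndarray) -> np.ndarray:
    """Map a flux vector to pool time derivatives (μmol/day)."""
    (
        diet_carb,
        diet_fat,
        prot_h,
        prot_p,
        up_glc_h,
        up_glc_p,
        up_tg_h,
        up_tg_p,
        glyc_h,
        glyc_p,
        box_h,
        box_p,
        dnl,
        vldl,
        resp_h,
        resp_p,
        loss_h,
        loss_p,
    ) = j
    return np.array(
        [
            diet_carb - up_glc_h - up_glc_p,
            diet_fat + vldl - up_tg_h - up_tg_p,
            up_glc_h - glyc_h,
            glyc_h + prot_h + ACOA_PER_TG * box_h - resp_h - dnl,
            up_tg_h + dnl / ACOA_PER_TG - box_h - vldl - loss_h,
            up_glc_p - glyc_p,
            glyc_p + prot_p + ACOA_PER_TG * box_p - resp_p,
            up_tg_p - box_p - loss_p,
        ]
    )


def build_odes(
    individual: VirtualIndividual,
    diet: DietSpec,
    f_act: float = 1.0,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Return the ODE right-hand side ``f(t, x) -> dx/dt`` for one individual.

    ``f_act`` multiplies the peripheral ACoA respiration flux only; every
    other flux follows the reduced kinetic scheme unchanged.
    """
    if f_act < 0:
        raise ValueError("activation factor f_act must be nonnegative")

    def rhs(t: float, x: np.ndarray) -> np.ndarray:  # noqa: ARG001 - autonomous
        return _rhs_from_fluxes(compute_fluxes(x, individual, diet, f_act))

    return rhs


def simulate_trajectory(
    individual: VirtualIndividual,
    diet: DietSpec,
    t_end: float = 90.0,
    f_act: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> Trajectory:
    """Integrate the model over ``[0, t_end]`` days on a daily grid.

    The grid has ``t_end + 1`` points (91 for the default three-month
    horizon).  Pools are clipped at zero before reporting; the integrator's
    tolerances keep any undershoot within reporting noise.
    """
    rhs = build_odes(individual, diet, f_act)
    t_eval = np.arange(0.0, t_end + 0.5, 1.0)
    x0 = individual.initial_state.as_array()
    sol = solve_ivp(
        rhs,
        (0.0, float(t_end)),
        x0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"integration failed for individual {individual.id!r}: {sol.message}"
        )
    states = np.maximum(sol.y.T, 0.0)
    flux = np.vstack([compute_fluxes(x, individual, diet, f_act) for x in states])
    return Trajectory(
        individual_id=individual.id,
        time=t_eval,
        pools=pd.DataFrame(states, columns=list(STATE_NAMES)),
        fluxes=pd.DataFrame(flux, columns=list(FLUX_NAMES)),
    )


def _residual(x: np.ndarray, rhs: Callable) -> float:
    dx = rhs(0.0, x)
    return float(np.max(np.abs(dx) / np.maximum(np.abs(x), 1.0)))


def compute_steady_state(
    individual: VirtualIndividual,
    diet: DietSpec,
    f_act: float = 1.0,
    x0: np.ndarray | None = None,
    tol: float = 1e-8,
    t_relax: float = 1e4,
    depletion_floor: float = DEPLETION_FLOOR,
) -> SteadyState:
    """Relax the model to steady state under a fixed diet and activation.

    Strategy: integrate the stiff system to ``t_relax`` days, then polish
    with a damped Newton solve on the right-hand side.  ``converged`` is
    True only if the normalised residual ``max_i |dx_i/dt|/max(x_i, 1)``
    falls below ``tol`` *and* no demanded pool is drained below the
    depletion floor.  A pool counts as depleted when it sits below the
    floor despite receiving positive inflow — the signature of respiration
    demand outrunning supply at large activation factors.
    """
    if f_act < 0:
        raise ValueError("activation factor f_act must be nonnegative")
    rhs = build_odes(individual, diet, f_act)
    x = individual.initial_state.as_array() if x0 is None else np.asarray(x0, float)

    sol = solve_ivp(rhs, (0.0, t_relax), x, method="LSODA", rtol=1e-10, atol=1e-10)
    if sol.success:
        x = np.maximum(sol.y[:, -1], 0.0)

    res = _residual(x, rhs)
    if res > tol:
        polish = root(lambda v: rhs(0.0, v), x, method="hybr", tol=1e-13)
        cand = polish.x
        if polish.success and np.all(cand > -1e-9):
            cand = np.maximum(cand, 0.0)
            if _residual(cand, rhs) < res:
                x = cand
                res = _residual(x, rhs)

    fluxes = compute_fluxes(x, individual, diet, f_act)
    inflow_per_pool = _pool_inflows(fluxes)
    depleted = np.any((x < depletion_floor) & (inflow_per_pool > depletion_floor))
    converged = bool(res <= tol and not depleted)
    return SteadyState(
        pools=pd.Series(x, index=list(STATE_NAMES)),
        fluxes=pd.Series(fluxes, index=list(FLUX_NAMES)),
        converged=converged,
        residual=res,
    )


def _pool_inflows(j: np.ndarray) -> np.ndarray:
    """Total inflow per pool (μmol of pool species/day), for depletion checks."""
    f = dict(zip(FLUX_NAMES, j))
    return np.array(
        [
            f["diet_carb"],
            f["diet_fat"] + f["vldl_secretion"],
            f["uptake_glc_hep"],
            f["glycolysis_hep"] + f["diet_protein_hep"] + ACOA_PER_TG * f["betaox_hep"],
            f["uptake_tg_hep"] + f["dnl"] / ACOA_PER_TG,
            f["uptake_glc_per"],
            f["glycolysis_per"] + f["diet_protein_per"] + ACOA_PER_TG * f["betaox_per"],
            f["uptake_tg_per"],
        ]
    )


def carbon_balance_audit(trajectory: Trajectory, diet: DietSpec) -> dict:
    """Trapezoidal carbon audit of a trajectory, independent of the solver.

    Carbon is counted in ACoA equivalents (glucose/G6P/ACoA ≡ 1, TG ≡ 21.4).
    Over the whole horizon, cumulative dietary inflow must equal cumulative
    respiration plus cumulative non-respiratory lipid turnover plus the net
    change in total pooled carbon.  Returns the four ledger entries and the
    relative closure error.
    """
    t = trajectory.time
    fx = trajectory.fluxes
    inflow = (
        fx["diet_carb"]
        + ACOA_PER_TG * fx["diet_fat"]
        + fx["diet_protein_hep"]
        + fx["diet_protein_per"]
    )
    respired = fx["resp_hep"] + fx["resp_per"]
    lost = ACOA_PER_TG * (fx["tg_loss_hep"] + fx["tg_loss_per"])

    cum_in = float(np.trapezoid(inflow, t))
    cum_resp = float(np.trapezoid(respired, t))
    cum_loss = float(np.trapezoid(lost, t))

    weights = np.array([POOL_ACOA_EQUIV[n] for n in STATE_NAMES])
    total_carbon = trajectory.pools.to_numpy() @ weights
    delta_pools = float(total_carbon[-1] - total_carbon[0])

    gap = cum_in - cum_resp - cum_loss - delta_pools
    scale = max(cum_in, 1.0)
    return {
        "cumulative_inflow": cum_in,
        "cumulative_respiration": cum_resp,
        "cumulative_loss": cum_loss,
        "delta_pools": delta_pools,
        "closure_error": gap,
        "relative_error": gap / scale,
    }


def individual_to_dict(individual: VirtualIndividual) -> dict:
    """JSON-ready mapping with field names exactly as on the dataclass."""
    out = {}
    for f in dc_fields(VirtualIndividual):
        v = getattr(individual, f.name)
        if isinstance(v, MetabolitePools):
            v = {n: getattr(v, n) for n in STATE_NAMES}
            v["plasma_volume_ml"] = individual.initial_state.plasma_volume_ml
        out[f.name] = v
    return out


def individual_from_dict(d: dict) -> VirtualIndividual:
    d = dict(d)
    init = d.pop("initial_state")
    pools = MetabolitePools(**init)
    return VirtualIndividual(initial_state=pools, **d)
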