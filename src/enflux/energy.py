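"""Energy accounting: from ACoA respiration fluxes to kcal/day.

Energy expenditure (EE) is the respiration of acetyl-CoA in the liver
(EE_hep) and the periphery (EE_per).  A respired ACoA flux in μmol/day is
converted to kcal/day by the TG equivalence chain: ÷21.4 (ACoA per TG),
×853·10⁻⁶ (g per μmol TG), ×9 (kcal per g fat).  The same factor is used
for all respired ACoA regardless of the substrate it derived from; this is
the model's deliberate convention, so substrate-specific caloric densities
appear only on the intake side of the energy balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import ACOA_PER_TG, KCAL_PER_UMOL_ACOA
from .model import SteadyState, Trajectory

__all__ = [
    "EnergyProfile",
    "EnergyBalance",
    "acoa_flux_to_kcal",
    "attribute_substrates",
    "energy_profile",
    "ee_series",
    "mean_ee",
    "energy_balance",
]


@dataclass(frozen=True)
class EnergyProfile:
    """Hepatic/peripheral/total EE plus substrate attribution."""

    ee_hep: float
    ee_per: float
    substrates_hep: tuple[float, float, float]  # (carb, fat, protein)
    substrates_per: tuple[float, float, float]

    @property
    def ee_total(self) -> float:
        return self.ee_hep + self.ee_per

    @property
    def peripheral_fraction(self) -> float:
        if self.ee_total == 0:
            raise ZeroDivisionError("peripheral fraction undefined at zero total EE")
        return self.ee_per / self.ee_total


@dataclass(frozen=True)
class EnergyBalance:
    intake: float
    expenditure: float

    @property
    def surplus(self) -> float:
        return self.intake - self.expenditure


def acoa_flux_to_kcal(flux: float | np.ndarray) -> float | np.ndarray:
    """Convert an ACoA respiration flux [μmol/day] to energy [kcal/day].

    Implements the stepwise chain μmol ACoA → μmol TG → g TG → kcal as a
    single linear factor; negative fluxes are rejected because respiration
    is unidirectional.
    """
    arr = np.asarray(flux, dtype=float)
    if np.any(arr < 0):
        raise ValueError("respiration flux must be nonnegative")
    out = arr * KCAL_PER_UMOL_ACOA
    return float(out) if np.isscalar(flux) or arr.ndim == 0 else out


def attribute_substrates(fluxes: pd.Series | dict, compartment: str) -> tuple[float, float, float]:
    """Fraction of a compartment's EE owed to (carb, fat, protein).

    Under the well-mixed ACoA pool assumption, respiration draws from the
    pool in proportion to its instantaneous inflows: glycolysis (carb),
    β-oxidation (fat, 21.4 ACoA per TG) and ketogenic dietary protein.
    """
    if compartment not in ("hep", "per"):
        raise ValueError("compartment must be 'hep' or 'per'")
    suffix = compartment
    try:
        carb = float(fluxes[f"glycolysis_{suffix}"])
        fat = ACOA_PER_TG * float(fluxes[f"betaox_{suffix}"])
        protein = float(fluxes[f"diet_protein_{suffix}"])
    except KeyError as exc:
        raise ValueError(f"flux record is missing {exc} for attribution") from exc
    if min(carb, fat, protein) < 0:
        raise ValueError("ACoA inflow fluxes must be nonnegative")
    total = carb + fat + protein
    if total <= 0:
        resp = float(fluxes.get(f"resp_{suffix}", 0.0))
        if resp > 0:
            raise ValueError(
                f"cannot attribute {compartment} respiration: all ACoA inflows are zero"
            )
        return (0.0, 0.0, 0.0)
    return (carb / total, fat / total, protein / total)


def _profile_from_fluxes(fluxes: pd.Series | dict) -> EnergyProfile:
    try:
        resp_h = float(fluxes["resp_hep"])
        resp_p = float(fluxes["resp_per"])
    except KeyError as exc:
        raise ValueError(f"flux record is missing respiration flux {exc}") from exc
    return EnergyProfile(
        ee_hep=acoa_flux_to_kcal(resp_h),
        ee_per=acoa_flux_to_kcal(resp_p),
        substrates_hep=attribute_substrates(fluxes, "hep"),
        substrates_per=attribute_substrates(fluxes, "per"),
    )


def energy_profile(source: Trajectory | SteadyState, day: float | None = None) -> EnergyProfile:
    """Energy profile of a steady state, or of a trajectory time point.

    For a trajectory the profile is evaluated at ``day`` (default: the
    final grid point, i.e. the fully developed three-month phenotype).
    """
    if isinstance(source, SteadyState):
        return _profile_from_fluxes(source.fluxes)
    if day is None:
        day = float(source.time[-1])
    return _profile_from_fluxes(source.flux_record(day))


def ee_series(trajectory: Trajectory) -> np.ndarray:
    """Total EE [kcal/day] at every grid point of a trajectory."""
    resp = trajectory.fluxes["resp_hep"].to_numpy() + trajectory.fluxes["resp_per"].to_numpy()
    return acoa_flux_to_kcal(resp)


def mean_ee(trajectory: Trajectory) -> float:
    """Time-averaged total EE [kcal/day] over the trajectory (trapezoidal)."""
    if len(trajectory.time) < 2:
        raise ValueError("mean EE needs at least two time points")
    ee = ee_series(trajectory)
    span = trajectory.time[-1] - trajectory.time[0]
    return float(np.trapezoid(ee, trajectory.time) / span)


def energy_balance(intake: float, expenditure: float) -> EnergyBalance:
    """Daily energy balance; surplus = intake − expenditure (may be negative)."""
    if intake < 0 or expenditure < 0:
        raise ValueError("intake and expenditure must be nonnegative")
    return EnergyBalance(intake=intake, expenditure=expenditure)
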