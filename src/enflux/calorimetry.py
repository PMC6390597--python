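"""Indirect calorimetry: gas exchange → substrate oxidation → energy.

A metabolic cage measures oxygen consumption VO₂ and carbon-dioxide
production VCO₂.  Their ratio, the respiratory quotient RQ = VCO₂/VO₂,
identifies the substrate mix being oxidised: pure glucose burns at RQ = 1,
pure fat at RQ = 0.71 and protein at RQ = 0.835.  Writing f_x for the
fraction of O₂ consumed by oxidising substrate x, the measurements pin
down three constraints:

* the RQ mixture,            RQ = Σ f_x · RQ_x
* normalisation,             f_glucose + f_fat + f_protein = 1
* constant protein share,    EE_protein = γ · EE_total,

where EE_x = VO₂ · f_x · RED_x and RED_x is the respiratory energy density
(kcal per litre O₂).  With α = γ/(1−γ)·RED_glucose/RED_protein and
β = γ/(1−γ)·RED_fat/RED_protein, the protein constraint becomes
f_protein = α·f_glucose + β·f_fat and the system solves in closed form:

    f_glucose = [RQ − (RQ_fat + β·RQ_protein)/(1+β)]
                / [RQ_glucose + α·RQ_protein − (1+α)(RQ_fat + β·RQ_protein)/(1+β)]
    f_fat     = (1 − (1+α)·f_glucose) / (1+β)

Note the (1+β) denominator of f_fat: it follows from eliminating
f_protein between the normalisation and the protein constraint,
(1+α)·f_glucose + (1+β)·f_fat = 1, and is required for all three
constraints to hold simultaneously whenever α ≠ β.  The closed form is
cross-checked against a direct 3×3 linear solve in the test suite.

The module also provides the inverse simulator (target oxidation → noisy
cage record) used to build synthetic calorimetry cohorts, and the 99.7%
(mean ± 3·SD) confidence intervals that define the physiological EE
ranges used for cohort stratification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CalorimetryConstants",
    "GasExchangeRecord",
    "OxidationResult",
    "PhysiologicalRange",
    "InfeasibleRQError",
    "respiratory_quotient",
    "feasible_rq_interval",
    "partition_substrates",
    "ee_from_gas_exchange",
    "physiological_range",
    "simulate_gas_exchange",
]

#: cage sampling interval [min] and protocol length [days]
SAMPLE_INTERVAL_MIN = 10.0
PROTOCOL_DAYS = 4
#: the first cage day is an acclimatisation day and is discarded
ACCLIMATISATION_DAYS = 1


class InfeasibleRQError(ValueError):
    """The measured RQ cannot arise from any admissible substrate mixture."""


@dataclass(frozen=True)
class CalorimetryConstants:
    """Substrate RQs, respiratory energy densities and the protein share γ.

    Defaults: γ = 0.2, RQ_glucose = 1, RQ_fat = 0.71, RQ_protein = 0.835,
    RED_protein = 4.17, RED_fat = 4.66, RED_glucose = 5.02 kcal/L O₂.
    """

    gamma: float = 0.2
    rq_glucose: float = 1.0
    rq_fat: float = 0.71
    rq_protein: float = 0.835
    red_glucose: float = 5.02
    red_fat: float = 4.66
    red_protein: float = 4.17

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")
        if min(self.red_glucose, self.red_fat, self.red_protein) <= 0:
            raise ValueError("respiratory energy densities must be positive")

    @property
    def alpha(self) -> float:
        return self.gamma / (1.0 - self.gamma) * self.red_glucose / self.red_protein

    @property
    def beta(self) -> float:
        return self.gamma / (1.0 - self.gamma) * self.red_fat / self.red_protein


@dataclass
class GasExchangeRecord:
    """One animal's metabolic-cage time series.

    ``vo2``/``vco2`` are instantaneous rates in L/day sampled on a 10-min
    grid (``time_min``) over the 4-day protocol.
    """

    animal_id: str
    time_min: np.ndarray
    vo2: np.ndarray                  # L O2/day
    vco2: np.ndarray                 # L CO2/day

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.vco2 = np.asarray(self.vco2, dtype=float)
        if not (len(self.time_min) == len(self.vo2) == len(self.vco2)):
            raise ValueError("time, vo2 and vco2 must have equal length")
        if np.any(self.vo2 <= 0):
            raise ValueError("vo2 must be strictly positive")
        if np.any(self.vco2 < 0):
            raise ValueError("vco2 must be nonnegative")


@dataclass(frozen=True)
class OxidationResult:
    """Substrate partition and energy decomposition of one record."""

    f_glucose: float
    f_fat: float
    f_protein: float
    ee_total: float                              # kcal/day
    energy_fractions: tuple[float, float, float]  # (glucose, fat, protein) of EE
    vo2: float = math.nan                        # L O2/day (aggregate)
    rq: float = math.nan


@dataclass(frozen=True)
class PhysiologicalRange:
    """Mean ± SD with the 99.7% (±3·SD) confidence interval, 1-decimal bounds."""

    mean: float
    sd: float
    ci_lower: float = field(init=False)
    ci_upper: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        object.__setattr__(self, "ci_lower", _round1(self.mean - 3.0 * self.sd))
        object.__setattr__(self, "ci_upper", _round1(self.mean + 3.0 * self.sd))


def _round1(x: float) -> float:
    """Round to one decimal, halves away from zero (printed-table convention)."""
    return math.floor(abs(x) * 10.0 + 0.5) / 10.0 * (1 if x >= 0 else -1)


def respiratory_quotient(vo2: float, vco2: float) -> float:
    """RQ = VCO₂/VO₂."""
    if vo2 <= 0:
        raise ValueError("vo2 must be strictly positive")
    if vco2 < 0:
        raise ValueError("vco2 must be nonnegative")
    return vco2 / vo2


def feasible_rq_interval(constants: CalorimetryConstants) -> tuple[float, float]:
    """The closed RQ interval achievable by an admissible substrate mixture.

    The extremes occur at f_glucose = 0 (all non-protein O₂ to fat) and
    f_fat = 0 (all non-protein O₂ to glucose) under the protein constraint.
    """
    a, b = constants.alpha, constants.beta
    lo = (constants.rq_fat + b * constants.rq_protein) / (1.0 + b)
    hi = (constants.rq_glucose + a * constants.rq_protein) / (1.0 + a)
    return (lo, hi)


def partition_substrates(
    rq: float, constants: CalorimetryConstants = CalorimetryConstants()
) -> tuple[float, float, float]:
    """Solve the substrate partition (f_glucose, f_fat, f_protein) from RQ.

    Raises
    ------
    InfeasibleRQError
        If ``rq`` lies outside the achievable mixture interval.
    """
    lo, hi = feasible_rq_interval(constants)
    eps = 1e-12
    if not (lo - eps <= rq <= hi + eps):
        raise InfeasibleRQError(
            f"RQ={rq:.4f} outside the admissible interval [{lo:.4f}, {hi:.4f}] "
            f"for gamma={constants.gamma}"
        )
    a, b = constants.alpha, constants.beta
    mix_fat = (constants.rq_fat + b * constants.rq_protein) / (1.0 + b)
    denom = constants.rq_glucose + a * constants.rq_protein - (1.0 + a) * mix_fat
    f_glc = (rq - mix_fat) / denom
    f_fat = (1.0 - (1.0 + a) * f_glc) / (1.0 + b)
    f_prot = a * f_glc + b * f_fat
    # clip the floating-point dust at the interval endpoints
    f_glc, f_fat, f_prot = (max(v, 0.0) for v in (f_glc, f_fat, f_prot))
    total = f_glc + f_fat + f_prot
    return (f_glc / total, f_fat / total, f_prot / total)


def _aggregate_record(
    record: GasExchangeRecord, discard_first_day: bool = True
) -> tuple[float, float]:
    """Mean VO₂ and VCO₂ (L/day) after discarding the acclimatisation day."""
    keep = (
        record.time_min >= ACCLIMATISATION_DAYS * 24 * 60
        if discard_first_day
        else np.ones_like(record.time_min, dtype=bool)
    )
    if not np.any(keep):
        raise ValueError("record has no samples after the acclimatisation day")
    return float(record.vo2[keep].mean()), float(record.vco2[keep].mean())


def ee_from_gas_exchange(
    record: GasExchangeRecord,
    constants: CalorimetryConstants = CalorimetryConstants(),
    discard_first_day: bool = True,
) -> OxidationResult:
    """Substrate oxidation and total EE from a cage record.

    Samples from the first cage day are discarded (acclimatisation), the
    remaining days are aggregated by their mean, and the energy
    decomposition EE_x = VO₂·f_x·RED_x is applied.
    """
    vo2, vco2 = _aggregate_record(record, discard_first_day)
    rq = respiratory_quotient(vo2, vco2)
    f_glc, f_fat, f_prot = partition_substrates(rq, constants)
    ee_glc = vo2 * f_glc * constants.red_glucose
    ee_fat = vo2 * f_fat * constants.red_fat
    ee_prot = vo2 * f_prot * constants.red_protein
    ee_total = ee_glc + ee_fat + ee_prot
    return OxidationResult(
        f_glucose=f_glc,
        f_fat=f_fat,
        f_protein=f_prot,
        ee_total=ee_total,
        energy_fractions=(ee_glc / ee_total, ee_fat / ee_total, ee_prot / ee_total),
        vo2=vo2,
        rq=rq,
    )


def physiological_range(mean: float, sd: float) -> PhysiologicalRange:
    """99.7% confidence interval (mean ± 3·SD) with 1-decimal printed bounds."""
    return PhysiologicalRange(mean=mean, sd=sd)


def simulate_gas_exchange(
    fractions: tuple[float, float, float],
    ee_total: float,
    constants: CalorimetryConstants = CalorimetryConstants(),
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    animal_id: str = "synthetic",
) -> GasExchangeRecord:
    """Inverse model: build a synthetic cage record realising a target mix.

    ``fractions`` are the O₂-consumption fractions (glucose, fat, protein).
    The noiseless record satisfies VO₂ = EE_total / Σ f_x·RED_x and
    VCO₂ = VO₂ · Σ f_x·RQ_x at every sample; multiplicative log-normal
    noise (mean-one) perturbs each 10-min sample independently, so the
    record's day-2..4 mean recovers the target in expectation.
    """
    f = np.asarray(fractions, dtype=float)
    if f.min() < 0 or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be nonnegative and sum to 1")
    if ee_total <= 0:
        raise ValueError("ee_total must be positive")
    red = np.array([constants.red_glucose, constants.red_fat, constants.red_protein])
    rqs = np.array([constants.rq_glucose, constants.rq_fat, constants.rq_protein])
    denom = float(f @ red)
    if denom <= 0:
        raise ValueError("mixture respiratory energy density is zero")
    vo2 = ee_total / denom
    rq = float(f @ rqs)

    n = int(PROTOCOL_DAYS * 24 * 60 / SAMPLE_INTERVAL_MIN)
    time_min = np.arange(n) * SAMPLE_INTERVAL_MIN
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise_sd > 0:
        sigma = math.sqrt(math.log(1.0 + noise_sd**2))
        mult_o2 = rng.lognormal(-sigma**2 / 2.0, sigma, size=n)
        mult_co2 = rng.lognormal(-sigma**2 / 2.0, sigma, size=n)
    else:
        mult_o2 = mult_co2 = np.ones(n)
    return GasExchangeRecord(
        animal_id=animal_id,
        time_min=time_min,
        vo2=vo2 * mult_o2,
        vco2=vo2 * rq * mult_co2,
    )
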