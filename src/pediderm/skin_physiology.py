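"""Adult reference skin parameters, maturation curves, and SC-thickness
uncertainty.

Four skin parameters mature with postnatal age: the thicknesses of the
stratum corneum (SC), viable epidermis and dermis, and SC hydration.  Each
is modelled as a child:adult ratio — a smooth function of postnatal age in
days that is pinned to exactly 1 at and beyond a cap age.  The default
curves are:

========================  ==========================================================  =========
parameter                 ratio(Age)                                                  cap (d)
========================  ==========================================================  =========
SC thickness (model 2)    2.662e-7 * Age^1.878 + 0.724                                1604
epidermis thickness       (1 - 0.634) * Age^5.363 / (18.702^5.363 + Age^5.363) + 0.634   —
dermis thickness          (1.5 - 0.407) * Age / (8974 + Age) + 0.407                  9883
SC hydration              -0.344 Age^0.245 - 17.585 Age^-0.0171 + 18.530              1182
========================  ==========================================================  =========

Hydration exceeds 1 around one month of age (infant skin is transiently
*more* hydrated than adult) and returns to 1 at its cap.  The hydration
polynomial diverges as Age -> 0 because of its negative exponent, so ages
are clamped to >= 1 day for that curve; the underlying measurements start
at one day of life.

Adult SC-thickness uncertainty: literature site-averaged measurements of the
partially hydrated SC give a log-normal coefficient of variation of ~0.43;
applied to the fully hydrated nominal 43 um this yields Lognormal(mu=3.68,
sigma^2=0.17), which is the sampling distribution used by the pediatric
Monte Carlo (after scaling by the SC maturation ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Literal, Mapping, Optional, Sequence

import numpy as np

ParameterId = Literal["sc_thickness", "ed_thickness", "de_thickness", "sc_hydration"]
FormName = Literal["sigmoid", "hill", "polynomial", "power"]

PARAMETER_IDS: tuple[str, ...] = (
    "sc_thickness",
    "ed_thickness",
    "de_thickness",
    "sc_hydration",
)


@dataclass(frozen=True)
class AdultReference:
    """Adult reference values; thicknesses in um, hydration on a ratio scale.

    The dermis default describes dermatomed (split-thickness) skin as
    mounted in Franz-cell permeation experiments, not full-thickness
    in vivo dermis.
    """

    h_sc_hydrated: float = 43.0
    h_ed: float = 60.0
    h_de: float = 500.0
    hydration_ref: float = 1.0

    def __post_init__(self) -> None:
        for name in ("h_sc_hydrated", "h_ed", "h_de", "hydration_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _evaluate_form(form: str, coeff: Mapping[str, float], age: np.ndarray) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    if form == "sigmoid":
        return coeff["a"] * age / (coeff["b"] + age) + coeff["c"]
    if form == "hill":
        n = coeff["n"]
        return coeff["a"] * age**n / (coeff["b"] ** n + age**n) + coeff["c"]
    if form == "polynomial":
        with np.errstate(divide="ignore"):
            return (
                coeff["a"] * age ** coeff["n"]
                + coeff["b"] * age ** coeff["m"]
                + coeff["c"]
            )
    if form == "power":
        return coeff["a"] * age ** coeff["b"] + coeff["c"]
    raise ValueError(f"unknown functional form {form!r}")


@dataclass(frozen=True)
class MaturationModel:
    """A child:adult ratio curve with a hard cap at adult parity."""

    parameter_id: str
    form: FormName
    coefficients: Dict[str, float] = field(default_factory=dict)
    cap_age: Optional[float] = None
    cap_value: float = 1.0
    min_age: float = 0.0  # ages clamped up to this before evaluation

    def __post_init__(self) -> None:
        for key, value in self.coefficients.items():
            if not math.isfinite(value):
                raise ValueError(f"coefficient {key} is not finite")

    def ratio(self, age_days: float | np.ndarray) -> float | np.ndarray:
        scalar = np.isscalar(age_days)
        age = np.atleast_1d(np.asarray(age_days, dtype=float))
        if np.any(age < 0):
            raise ValueError("age_days must be >= 0")
        age = np.maximum(age, self.min_age)
        out = _evaluate_form(self.form, self.coefficients, age)
        if self.cap_age is not None:
            out = np.where(age >= self.cap_age, self.cap_value, out)
        return float(out[0]) if scalar else out


#: Final published maturation curves. SC thickness has two candidates; the
#: default (model 2) excludes a neonatal dataset whose SC readings exceeded
#: adult values, contradicting every other source.
SC_MATURATION_MODEL_2 = MaturationModel(
    "sc_thickness", "power", {"a": 2.662e-7, "b": 1.878, "c": 0.724}, cap_age=1604.0
)
SC_MATURATION_MODEL_1 = MaturationModel(
    "sc_thickness",
    "polynomial",
    {"a": 2.401e-7, "n": 2.000, "b": -99.43, "m": 2.071e-3, "c": 101.4},
    cap_age=1510.0,
)
ED_MATURATION = MaturationModel(
    "ed_thickness", "hill", {"a": 1.0 - 0.634, "b": 18.702, "n": 5.363, "c": 0.634}
)
DE_MATURATION = MaturationModel(
    "de_thickness", "sigmoid", {"a": 1.5 - 0.407, "b": 8.974e3, "c": 0.407}, cap_age=9883.0
)
HYDRATION_MATURATION = MaturationModel(
    "sc_hydration",
    "polynomial",
    {"a": -0.344, "n": 0.245, "b": -17.585, "m": -0.0171, "c": 18.530},
    cap_age=1182.0,
    min_age=1.0,
)


def default_maturation_models(sc_model: str = "model2") -> Dict[str, MaturationModel]:
    """The packaged curve set, keyed by parameter id."""
    sc = {"model1": SC_MATURATION_MODEL_1, "model2": SC_MATURATION_MODEL_2}[sc_model]
    return {
        "sc_thickness": sc,
        "ed_thickness": ED_MATURATION,
        "de_thickness": DE_MATURATION,
        "sc_hydration": HYDRATION_MATURATION,
    }


def maturation_ratio(model: MaturationModel, age_days: float) -> float:
    """Evaluate a maturation curve at a postnatal age in days."""
    if model.parameter_id not in PARAMETER_IDS:
        raise ValueError(f"unknown parameter_id {model.parameter_id!r}")
    return model.ratio(age_days)


@dataclass(frozen=True)
class AgeDependentParameters:
    """The age-conditional parameter set PA(Age): geometry plus hydration."""

    age_days: float
    h_sc: float
    h_ed: float
    h_de: float
    hydration_ratio: float

    def __post_init__(self) -> None:
        for name in ("h_sc", "h_ed", "h_de"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def pediatric_parameters(
    adult: AdultReference,
    models: Mapping[str, MaturationModel],
    age_days: float,
) -> AgeDependentParameters:
    """Scale the adult reference by each maturation ratio at the given age."""
    missing = set(PARAMETER_IDS) - set(models)
    if missing:
        raise ValueError(f"missing maturation models for {sorted(missing)}")
    return AgeDependentParameters(
        age_days=age_days,
        h_sc=adult.h_sc_hydrated * models["sc_thickness"].ratio(age_days),
        h_ed=adult.h_ed * models["ed_thickness"].ratio(age_days),
        h_de=adult.h_de * models["de_thickness"].ratio(age_days),
        hydration_ratio=adult.hydration_ref * models["sc_hydration"].ratio(age_days),
    )


@dataclass(frozen=True)
class LognormalSpec:
    """Log-scale mean and variance of a lognormal distribution."""

    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")

    @property
    def arithmetic_mean(self) -> float:
        return math.exp(self.mu + self.sigma2 / 2.0)


def lognormal_from_mean_cv(mean: float, cv: float) -> LognormalSpec:
    """Lognormal spec with the given arithmetic mean and coefficient of variation."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    sigma2 = math.log1p(cv**2)
    return LognormalSpec(mu=math.log(mean) - sigma2 / 2.0, sigma2=sigma2)


def estimate_cv_lognormal(values: Sequence[float]) -> float:
    """CV of lognormally distributed values from the n-1 variance of their logs."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    if np.any(arr <= 0):
        raise ValueError("all values must be positive")
    s2 = float(np.var(np.log(arr), ddof=1))
    return math.sqrt(math.expm1(s2))


def sample_sc_thickness(
    spec: LognormalSpec,
    model: MaturationModel,
    age_days: float,
    n: int,
    seed: int,
) -> np.ndarray:
    """Draw hydrated SC thicknesses (um) at a given age.

    Draws from the adult lognormal, then scales each draw by the SC
    maturation ratio — the age-conditional distribution p(PA*|Age).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    adult_draws = np.exp(rng.normal(spec.mu, math.sqrt(spec.sigma2), size=n))
    return adult_draws * model.ratio(age_days)
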