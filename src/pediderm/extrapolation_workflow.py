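"""Adult-to-child extrapolation: fit the adult in vitro model, then predict
neonatal flux with Monte Carlo uncertainty.

The evaluation pipeline has three steps:

1. parameterize the adult model (age 30 years) with the compound's
   physicochemical properties and nominal QSPRs;
2. fit the three uncertain SC parameters (log10 k_trans, log10 PC_pro/w,
   log10 K_lip/w) — each confined to its published uncertainty box — so
   that simulated terminal flux and final receptor accumulation match the
   observed adult values (multi-start least squares on relative errors;
   with three parameters against two observations the solution is
   non-unique, so the contract is output-matching, with ties broken by
   proximity to the nominal values);
3. predict the child: repeated simulations at the subject's postnatal age,
   each drawing a hydrated SC thickness from the adult lognormal scaled by
   the SC maturation ratio, the other layer thicknesses scaling
   deterministically.  Summaries are the geometric mean terminal flux and
   the empirical 2.5th-97.5th percentile interval.

Predictive performance is scored as fold error = predicted / observed flux.
A local sensitivity analysis (normalized central differences) and its
child-vs-adult differential complete the workflow.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .compound_qspr import (
    Compound,
    LayerCoefficients,
    QsprParameterSet,
    layer_coefficients,
    qspr_bounds,
)
from .config import RunConfig
from .permeation_solver import (
    ExposureScenario,
    SimulationResult,
    SolverError,
    build_domain,
    simulate,
    terminal_flux,
)
from .skin_physiology import (
    AdultReference,
    AgeDependentParameters,
    LognormalSpec,
    MaturationModel,
    default_maturation_models,
    pediatric_parameters,
    sample_sc_thickness,
)

logger = logging.getLogger(__name__)

SENSITIVITY_PARAMETERS = (
    "d_sc",
    "d_ed",
    "d_de",
    "k_sc_w",
    "k_ed_w",
    "k_de_w",
    "h_sc",
    "h_ed",
    "h_de",
)


def adult_reference_from(config: RunConfig) -> AdultReference:
    return AdultReference(
        h_sc_hydrated=config.adult.h_sc_um,
        h_ed=config.adult.h_ed_um,
        h_de=config.adult.h_de_um,
        hydration_ref=config.adult.hydration_ref,
    )


def _subject_parameters(
    config: RunConfig,
    models: Mapping[str, MaturationModel],
    age_days: float,
    h_sc_override: Optional[float] = None,
) -> AgeDependentParameters:
    params = pediatric_parameters(adult_reference_from(config), models, age_days)
    if config.maturation.in_vitro_full_hydration:
        params = replace(params, hydration_ratio=1.0)
    if h_sc_override is not None:
        params = replace(params, h_sc=h_sc_override)
    return params


def run_simulation(
    compound: Compound,
    qspr: QsprParameterSet,
    scenario: ExposureScenario,
    params: AgeDependentParameters,
    config: RunConfig,
) -> SimulationResult:
    """Compose coefficients, grid the domain and integrate one exposure."""
    coeffs = layer_coefficients(
        compound, qspr, params, config, vehicle_ph=scenario.vehicle_ph
    )
    domain = build_domain(coeffs, params, config.numerics)
    return simulate(domain, scenario, config.numerics)


@dataclass(frozen=True)
class FitSpec:
    """Targets and controls for the adult parameter identification step."""

    observed_flux: float
    observed_accumulation: float
    starts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.observed_flux <= 0 or self.observed_accumulation <= 0:
            raise ValueError("observed adult flux and accumulation must be > 0")
        if self.starts < 1:
            raise ValueError("starts must be >= 1")


@dataclass(frozen=True)
class AdultFit:
    """Fitted P* with its objective value and reproduced outputs."""

    qspr: QsprParameterSet
    objective: float
    flux: float
    accumulation: float
    warning: bool


def fit_adult(
    compound: Compound,
    scenario: ExposureScenario,
    fit_spec: FitSpec,
    config: RunConfig,
    models: Optional[Mapping[str, MaturationModel]] = None,
) -> AdultFit:
    """Fit the P* triple to the observed adult flux and accumulation.

    Minimizes the sum of squared relative errors of (terminal flux, final
    accumulation), multi-started from random points inside the QSPR
    uncertainty box.  The best objective wins; near-ties go to the solution
    closest to the nominal parameter values.
    """
    models = models or default_maturation_models(config.maturation.sc_model)
    params = _subject_parameters(config, models, config.workflow.adult_age_days)
    lower, upper = qspr_bounds(compound)
    nominal = QsprParameterSet.nominal(compound).as_array()

    def residuals(x: np.ndarray) -> np.ndarray:
        qspr = QsprParameterSet.from_array(x, "sampled")
        try:
            result = run_simulation(compound, qspr, scenario, params, config)
        except SolverError:
            return np.array([1e3, 1e3])
        return np.array(
            [
                (terminal_flux(result) - fit_spec.observed_flux) / fit_spec.observed_flux,
                (result.accumulation[-1] - fit_spec.observed_accumulation)
                / fit_spec.observed_accumulation,
            ]
        )

    rng = np.random.default_rng(fit_spec.seed)
    solutions: List[Tuple[float, float, np.ndarray]] = []
    for i in range(fit_spec.starts):
        x0 = nominal if i == 0 else rng.uniform(lower, upper)
        if np.allclose(lower, upper):
            solutions.append((float(np.sum(residuals(nominal) ** 2)), 0.0, nominal))
            break
        try:
            sol = least_squares(
                residuals,
                np.clip(x0, lower, upper),
                bounds=(lower, upper),
                method="trf",
                xtol=1e-10,
                max_nfev=60,
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.debug("fit start %d failed: %s", i, exc)
            continue
        obj = float(np.sum(sol.fun**2))
        dist = float(np.linalg.norm(sol.x - nominal))
        solutions.append((obj, dist, sol.x))
    if not solutions:
        raise RuntimeError(f"all {fit_spec.starts} fit starts failed for {compound.name}")

    # best objective; within numerical ties prefer proximity to nominal
    best_obj = min(s[0] for s in solutions)
    tied = [s for s in solutions if s[0] <= best_obj * (1 + 1e-6) + 1e-12]
    tied.sort(key=lambda s: s[1])
    obj, _, x = tied[0]

    qspr = QsprParameterSet.from_array(x, "fitted")
    result = run_simulation(compound, qspr, scenario, params, config)
    flux = terminal_flux(result)
    acc = float(result.accumulation[-1])
    warn_tol = config.workflow.fit_warn_rel_error
    warning = (
        abs(flux - fit_spec.observed_flux) / fit_spec.observed_flux > warn_tol
        or abs(acc - fit_spec.observed_accumulation) / fit_spec.observed_accumulation
        > warn_tol
    )
    if warning:
        logger.warning(
            "%s adult fit misses observations by more than %.0f%% "
            "(flux %.3g vs %.3g, accumulation %.3g vs %.3g)",
            compound.name,
            warn_tol * 100,
            flux,
            fit_spec.observed_flux,
            acc,
            fit_spec.observed_accumulation,
        )
    return AdultFit(qspr=qspr, objective=obj, flux=flux, accumulation=acc, warning=warning)


@dataclass(frozen=True)
class PredictionResult:
    """Monte Carlo terminal-flux prediction at one postnatal age."""

    age_days: float
    samples: np.ndarray
    geometric_mean: float
    ci_low: float
    ci_high: float
    seed: int
    n_failed: int = 0

    def __post_init__(self) -> None:
        if self.samples.size < 2:
            raise ValueError("need at least 2 Monte Carlo samples")


def predict_child(
    compound: Compound,
    qspr: QsprParameterSet,
    scenario: ExposureScenario,
    age_days: float,
    sc_spec: LognormalSpec,
    config: RunConfig,
    models: Optional[Mapping[str, MaturationModel]] = None,
    n: Optional[int] = None,
    seed: int = 0,
    sc_multiplier: float = 1.0,
) -> PredictionResult:
    """Simulate ``n`` subjects at one age, sampling hydrated SC thickness.

    ``sc_multiplier`` optionally thins the sampled SC further (e.g. for
    exploratory preterm runs); it defaults to 1 (no adjustment).
    """
    n = n or config.workflow.mc_samples
    if n < 2:
        raise ValueError("n must be >= 2")
    models = models or default_maturation_models(config.maturation.sc_model)
    draws = sample_sc_thickness(sc_spec, models["sc_thickness"], age_days, n, seed)
    draws = draws * sc_multiplier

    fluxes, failed = [], 0
    for h_sc in draws:
        params = _subject_parameters(config, models, age_days, h_sc_override=float(h_sc))
        try:
            result = run_simulation(compound, qspr, scenario, params, config)
        except SolverError as exc:
            failed += 1
            logger.warning("dropped MC sample (h_sc=%.2f um): %s", h_sc, exc)
            continue
        fluxes.append(terminal_flux(result))
    if failed > 0.1 * n:
        raise RuntimeError(f"{failed}/{n} Monte Carlo simulations failed")

    samples = np.array(fluxes)
    positive = samples[samples > 0]
    if positive.size < 2:
        raise RuntimeError("too few positive flux samples for a geometric mean")
    geo = float(np.exp(np.mean(np.log(positive))))
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return PredictionResult(
        age_days=age_days,
        samples=samples,
        geometric_mean=geo,
        ci_low=float(lo),
        ci_high=float(hi),
        seed=seed,
        n_failed=failed,
    )


def fold_error(predicted: float, observed: float) -> float:
    """Predicted / observed flux; 1 means a perfect prediction."""
    if observed <= 0:
        raise ValueError("observed flux must be > 0")
    return predicted / observed


@dataclass(frozen=True)
class EvaluationRecord:
    """One infant-experiment row of the evaluation report."""

    compound: str
    gestational_age_w: float
    postnatal_age_days: float
    observed_flux: float
    predicted_geomean: float
    ci_low: float
    ci_high: float
    fold_error: float
    preterm: bool


def evaluate(
    compounds: Mapping[str, Compound],
    adult_rows: Sequence[Mapping],
    infant_rows: Sequence[Mapping],
    config: RunConfig,
    seed: int = 0,
    sc_spec: Optional[LognormalSpec] = None,
) -> List[EvaluationRecord]:
    """Run the full adult-fit + child-prediction pipeline over a study table.

    ``adult_rows`` and ``infant_rows`` are mappings with the scenario and
    observation fields produced by the fixture loaders (see
    :mod:`pediderm.fixtures`).  One adult fit per compound; one Monte Carlo
    prediction per infant row.  Deterministic for a fixed ``seed``.
    """
    from .fixtures import default_sc_lognormal, scenario_from_row  # cycle guard

    sc_spec = sc_spec or default_sc_lognormal()
    models = default_maturation_models(config.maturation.sc_model)

    fits: Dict[str, AdultFit] = {}
    for row in adult_rows:
        name = row["compound"]
        compound = compounds[name]
        scenario = scenario_from_row(row, compound, config)
        spec = FitSpec(
            observed_flux=float(row["observed_flux_ug_cm2_h"]),
            observed_accumulation=float(row["observed_Q_ug_cm2"]),
            starts=config.workflow.fit_starts,
            seed=seed + zlib.crc32(name.encode()) % 100_000,
        )
        fits[name] = fit_adult(compound, scenario, spec, config, models)

    records: List[EvaluationRecord] = []
    for i, row in enumerate(infant_rows):
        name = row["compound"]
        compound = compounds[name]
        scenario = scenario_from_row(row, compound, config)
        age_days = float(row["postnatal_age_days"])
        ga = float(row["gestational_age_w"])
        preterm = ga < 37.0
        prediction = predict_child(
            compound,
            fits[name].qspr,
            scenario,
            age_days,
            sc_spec,
            config,
            models=models,
            seed=seed + 1000 + i,
            sc_multiplier=config.maturation.preterm_sc_multiplier if preterm else 1.0,
        )
        observed = float(row["observed_flux_ug_cm2_h"])
        records.append(
            EvaluationRecord(
                compound=name,
                gestational_age_w=ga,
                postnatal_age_days=age_days,
                observed_flux=observed,
                predicted_geomean=prediction.geometric_mean,
                ci_low=prediction.ci_low,
                ci_high=prediction.ci_high,
                fold_error=fold_error(prediction.geometric_mean, observed),
                preterm=preterm,
            )
        )
    return records


@dataclass(frozen=True)
class SensitivityReport:
    """Normalized local sensitivities of yJ and yQ at one age."""

    age_days: float
    coefficients: Dict[str, Tuple[float, float]]  # param -> (S_flux, S_Q)
    skipped: Tuple[str, ...] = ()


def local_sensitivity(
    compound: Compound,
    qspr: QsprParameterSet,
    scenario: ExposureScenario,
    age_days: float,
    config: RunConfig,
    parameters: Sequence[str] = SENSITIVITY_PARAMETERS,
    perturbation: float = 0.1,
    models: Optional[Mapping[str, MaturationModel]] = None,
) -> SensitivityReport:
    """Central-difference sensitivities S = (dY/Y)/(dP/P) for yJ and yQ.

    Perturbs the lumped layer coefficients and thicknesses directly, holding
    everything else fixed (so e.g. thinning h_sc does not also change D_sc).
    """
    unknown = set(parameters) - set(SENSITIVITY_PARAMETERS)
    if unknown:
        raise ValueError(f"unknown sensitivity parameters {sorted(unknown)}")
    models = models or default_maturation_models(config.maturation.sc_model)
    params = _subject_parameters(config, models, age_days)
    base_coeffs = layer_coefficients(
        compound, qspr, params, config, vehicle_ph=scenario.vehicle_ph
    )

    def outputs(coeffs: LayerCoefficients, p: AgeDependentParameters) -> Tuple[float, float]:
        domain = build_domain(coeffs, p, config.numerics)
        result = simulate(domain, scenario, config.numerics)
        return terminal_flux(result), float(result.accumulation[-1])

    j0, q0 = outputs(base_coeffs, params)
    coefficients: Dict[str, Tuple[float, float]] = {}
    skipped: List[str] = []
    for name in parameters:
        values = []
        ok = True
        for sign in (+1.0, -1.0):
            factor = 1.0 + sign * perturbation
            if factor <= 0:
                ok = False
                break
            if name.startswith("h_"):
                layer = name[2:]
                p = replace(params, **{f"h_{layer}": getattr(params, f"h_{layer}") * factor})
                c = base_coeffs
            else:
                c = replace(base_coeffs, **{name: getattr(base_coeffs, name) * factor})
                p = params
            values.append(outputs(c, p))
        if not ok:
            skipped.append(name)
            continue
        (j_hi, q_hi), (j_lo, q_lo) = values
        s_j = ((j_hi - j_lo) / j0) / (2 * perturbation) if j0 > 0 else 0.0
        s_q = ((q_hi - q_lo) / q0) / (2 * perturbation) if q0 > 0 else 0.0
        coefficients[name] = (s_j, s_q)
    return SensitivityReport(
        age_days=age_days, coefficients=coefficients, skipped=tuple(skipped)
    )


def age_differential_sensitivity(
    child: SensitivityReport,
    adult: SensitivityReport,
    threshold: float = 0.15,
) -> List[str]:
    """Parameters whose flux sensitivity differs by >= threshold child vs adult."""
    if set(child.coefficients) != set(adult.coefficients):
        raise ValueError("child and adult reports cover different parameter lists")
    flagged = []
    for name, (s_child, _) in child.coefficients.items():
        s_adult = adult.coefficients[name][0]
        if abs(s_child - s_adult) >= threshold:
            flagged.append(name)
    return sorted(flagged)
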