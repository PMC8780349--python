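"""Adult fit, pediatric Monte Carlo prediction, fold error, sensitivity."""

import numpy as np
import pytest

from pediderm import RunConfig
from pediderm.compound_qspr import QsprParameterSet
from pediderm.extrapolation_workflow import (
    FitSpec,
    SensitivityReport,
    _subject_parameters,
    age_differential_sensitivity,
    evaluate,
    fit_adult,
    fold_error,
    local_sensitivity,
    predict_child,
    run_simulation,
)
from pediderm.fixtures import default_sc_lognormal, scenario_from_row
from pediderm.permeation_solver import terminal_flux
from pediderm.skin_physiology import LognormalSpec, default_maturation_models


@pytest.fixture(scope="module")
def fast_config():
    # fewer starts keep unit tests quick; the acceptance suite uses defaults
    return RunConfig.model_validate({"workflow": {"fit_starts": 4}})


@pytest.fixture(scope="module")
def pheno_setup(fast_config):
    from pediderm.fixtures import load_compounds, load_fixture

    compounds = load_compounds()
    row = (
        load_fixture("adult_observations").set_index("compound").loc["phenobarbital"]
    ).to_dict()
    row["compound"] = "phenobarbital"
    scenario = scenario_from_row(row, compounds["phenobarbital"], fast_config)
    return compounds["phenobarbital"], scenario, row


class TestFitAdult:
    def test_synthetic_truth_recovered_as_outputs(self, fast_config, pheno_setup):
        """Feeding the model its own outputs back as observations reproduces
        those outputs (parameters may be non-unique)."""
        compound, scenario, _ = pheno_setup
        models = default_maturation_models()
        truth = QsprParameterSet.nominal(compound)
        params = _subject_parameters(fast_config, models, 10950.0)
        result = run_simulation(compound, truth, scenario, params, fast_config)
        spec = FitSpec(
            observed_flux=terminal_flux(result),
            observed_accumulation=float(result.accumulation[-1]),
            starts=4,
            seed=11,
        )
        fit = fit_adult(compound, scenario, spec, fast_config)
        assert fit.flux == pytest.approx(spec.observed_flux, rel=0.01)
        assert fit.accumulation == pytest.approx(spec.observed_accumulation, rel=0.01)

    def test_phenobarbital_adult_flux_target(self, fast_config, pheno_setup):
        """The published adult phenobarbital flux (0.1 ug/cm^2/h) is matched
        within 20% by the fitted model."""
        compound, scenario, row = pheno_setup
        spec = FitSpec(
            observed_flux=float(row["observed_flux_ug_cm2_h"]),
            observed_accumulation=float(row["observed_Q_ug_cm2"]),
            starts=4,
            seed=1,
        )
        fit = fit_adult(compound, scenario, spec, fast_config)
        assert fit.flux == pytest.approx(0.1, rel=0.2)
        assert not fit.warning

    def test_degenerate_box_returns_nominal(self, fast_config, pheno_setup, monkeypatch):
        compound, scenario, _ = pheno_setup
        nominal = QsprParameterSet.nominal(compound).as_array()
        monkeypatch.setattr(
            "pediderm.extrapolation_workflow.qspr_bounds",
            lambda c: (nominal.copy(), nominal.copy()),
        )
        spec = FitSpec(observed_flux=0.1, observed_accumulation=0.91, starts=3, seed=0)
        fit = fit_adult(compound, scenario, spec, fast_config)
        np.testing.assert_allclose(fit.qspr.as_array(), nominal)


class TestPredictChild:
    def test_zero_variance_collapses_interval(self, fast_config, pheno_setup):
        compound, scenario, _ = pheno_setup
        qspr = QsprParameterSet.nominal(compound)
        spec = LognormalSpec(np.log(43.0), 0.0)
        pred = predict_child(
            compound, qspr, scenario, 5.0, spec, fast_config, n=10, seed=3
        )
        assert pred.ci_low == pytest.approx(pred.ci_high, rel=1e-9)
        assert pred.geometric_mean == pytest.approx(pred.ci_low, rel=1e-9)

    def test_adult_age_median_matches_median_thickness_flux(self, fast_config, pheno_setup):
        """At adult age the median sampled flux equals the deterministic flux
        at the median sampled thickness (flux is monotone in thickness, so
        medians map through exactly; only MC noise remains)."""
        compound, scenario, _ = pheno_setup
        qspr = QsprParameterSet.nominal(compound)
        models = default_maturation_models()
        spec = default_sc_lognormal()
        params = _subject_parameters(
            fast_config, models, 10950.0, h_sc_override=float(np.exp(spec.mu))
        )
        flux_at_median_h = terminal_flux(
            run_simulation(compound, qspr, scenario, params, fast_config)
        )
        pred = predict_child(
            compound, qspr, scenario, 10950.0, spec, fast_config, n=400, seed=4
        )
        assert float(np.median(pred.samples)) == pytest.approx(flux_at_median_h, rel=0.15)

    def test_neonate_flux_exceeds_adult(self, fast_config, pheno_setup):
        compound, scenario, _ = pheno_setup
        qspr = QsprParameterSet.nominal(compound)
        models = default_maturation_models()
        params = _subject_parameters(fast_config, models, 10950.0)
        adult_flux = terminal_flux(
            run_simulation(compound, qspr, scenario, params, fast_config)
        )
        pred = predict_child(
            compound, qspr, scenario, 5.0, default_sc_lognormal(), fast_config, seed=5
        )
        assert pred.geometric_mean > adult_flux

    def test_geomean_inside_interval_and_reproducible(self, fast_config, pheno_setup):
        compound, scenario, _ = pheno_setup
        qspr = QsprParameterSet.nominal(compound)
        a = predict_child(
            compound, qspr, scenario, 5.0, default_sc_lognormal(), fast_config,
            n=50, seed=6,
        )
        b = predict_child(
            compound, qspr, scenario, 5.0, default_sc_lognormal(), fast_config,
            n=50, seed=6,
        )
        assert a.ci_low <= a.geometric_mean <= a.ci_high
        np.testing.assert_array_equal(a.samples, b.samples)


class TestFoldError:
    def test_identity(self):
        assert fold_error(0.11, 0.11) == 1.0

    def test_half(self):
        assert fold_error(0.13, 0.26) == pytest.approx(0.5)

    def test_nonpositive_observed_rejected(self):
        with pytest.raises(ValueError):
            fold_error(0.1, 0.0)


class TestSensitivity:
    @pytest.fixture(scope="class")
    def adult_report(self, fast_config, pheno_setup):
        compound, scenario, _ = pheno_setup
        return local_sensitivity(
            compound, QsprParameterSet.nominal(compound), scenario, 10950.0, fast_config
        )

    def test_sc_dominates_thickness_sensitivities(self, adult_report):
        s = {k: abs(v[0]) for k, v in adult_report.coefficients.items()}
        assert s["h_sc"] == max(s["h_sc"], s["h_ed"], s["h_de"])
        assert s["k_ed_w"] < 0.1  # negligible when ED resistance is negligible

    def test_membrane_limit_signs(self):
        """In the SC-membrane steady-state limit S(D_sc) ~ +1, S(h_sc) ~ -1."""
        from pediderm.compound_qspr import Compound
        from pediderm.permeation_solver import ExposureScenario

        config = RunConfig()
        compound = Compound("probe", 300.0, 1.0, None, "neutral", 1000.0)
        scenario = ExposureScenario(
            dose_per_area=1e6,
            duration_h=600.0,
            donor_regime="saturated",
            solubility_in_vehicle=100.0,
        )
        report = local_sensitivity(
            compound, QsprParameterSet.nominal(compound), scenario, 10950.0, config,
            parameters=("d_sc", "h_sc"),
        )
        assert report.coefficients["d_sc"][0] == pytest.approx(1.0, abs=0.1)
        assert report.coefficients["h_sc"][0] == pytest.approx(-1.0, abs=0.15)

    def test_age_differential_flagging(self, adult_report):
        shifted = SensitivityReport(
            age_days=5.0,
            coefficients={
                k: (v[0] + (0.3 if k == "h_sc" else 0.0), v[1])
                for k, v in adult_report.coefficients.items()
            },
        )
        assert age_differential_sensitivity(shifted, adult_report) == ["h_sc"]
        assert age_differential_sensitivity(adult_report, adult_report) == []

    def test_mismatched_reports_rejected(self, adult_report):
        partial = SensitivityReport(5.0, {"h_sc": (0.0, 0.0)})
        with pytest.raises(ValueError):
            age_differential_sensitivity(partial, adult_report)


def test_evaluation_pipeline_deterministic(fast_config, compounds, adult_rows, infant_rows):
    """Fixed seeds give bit-identical evaluation records end to end."""
    rows = [r for r in infant_rows if r["compound"] == "diamorphine"]
    adults = [r for r in adult_rows if r["compound"] == "diamorphine"]
    cfg = RunConfig.model_validate({"workflow": {"fit_starts": 3, "mc_samples": 20}})
    a = evaluate(compounds, adults, rows, cfg, seed=7)
    b = evaluate(compounds, adults, rows, cfg, seed=7)
    assert a == b
    assert all(r.fold_error == r.predicted_geomean / r.observed_flux for r in a)
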