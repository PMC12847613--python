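"""MAP objective, optimizer behaviour, and curvature diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

from tacpredict.errors import ErrorModelSpec
from tacpredict.estimation import (
    BayesPrior,
    FitInputError,
    FitOptions,
    FitResult,
    PatientModelContext,
    covariance_from_curvature,
    fit_map,
    goodness_of_fit,
    objective,
)
from tacpredict.measurements import MeasurementSet, measurement_set_from_records
from tacpredict.parameters import FitParameters, PARAMETER_NAMES


class StubContext:
    """Analytic stand-in for the PBPK forward model (synthetic; test-only).

    f_i = p[0] * exp(-p[1]/10 * t_i): only the first two parameters matter,
    which keeps optimizer tests fast and their optima known in closed form.
    """

    def __init__(self, times):
        self.times = np.asarray(times, dtype=float)
        self.n_simulations = 0
        self.rtol = 1e-6
        self.atol = 1e-9

    def predict(self, params, data):
        p = params.to_array() if isinstance(params, FitParameters) else np.asarray(params)
        self.n_simulations += 1
        return p[0] * np.exp(-p[1] / 10.0 * self.times)


def _records(times, values, phase="diagnostic", cls="organ"):
    return measurement_set_from_records(
        [
            {
                "region": "kidneys",
                "tissue_class": cls,
                "phase": phase,
                "modality": "PET",
                "time_min": t,
                "activity_MBq": y,
            }
            for t, y in zip(times, values)
        ]
    )


def _uniform_prior(mean_scale=1.0, cv=0.5):
    base = FitParameters.default().to_dict()
    return BayesPrior(
        mean={k: v * mean_scale for k, v in base.items()},
        sd={k: cv * v * mean_scale for k, v in base.items()},
    )


class TestObjective:
    def test_zero_residual_leaves_only_log_terms(self):
        times = [1.0, 2.0, 3.0]
        ctx = StubContext(times)
        f = ctx.predict(FitParameters.default(), None)
        data = _records(times, f)
        spec = ErrorModelSpec.uniform("model_based", "two_b", 0.2)
        expected = float(np.sum(np.log((0.2 * f) ** 2)))
        assert objective(FitParameters.default(), data, spec, None, ctx) == pytest.approx(expected, rel=1e-12)

    def test_prior_at_mean_with_empty_data_is_zero(self):
        ctx = StubContext([])
        empty = MeasurementSet(pd.DataFrame(columns=["region", "tissue_class", "phase", "modality", "time_min", "activity_MBq"]))
        prior = _uniform_prior()
        assert objective(FitParameters.default(), empty, ErrorModelSpec.uniform("data_based", "two_b", 0.2), prior, ctx) == 0.0

    def test_hand_computed_three_records_with_penalty(self):
        times = [1.0, 5.0, 9.0]
        ctx = StubContext(times)
        p = FitParameters.default()
        f = ctx.predict(p, None)
        y = f * np.array([1.1, 0.9, 1.05])
        data = _records(times, y)
        b = 0.25
        spec = ErrorModelSpec.uniform("data_based", "two_b", b)
        prior = _uniform_prior(mean_scale=1.3, cv=0.4)
        sigma = b * y
        expected = float(np.sum((y - f) ** 2 / sigma**2 + np.log(sigma**2)))
        s_log = math.sqrt(math.log1p(0.4**2))
        for name in PARAMETER_NAMES:
            expected += (math.log(getattr(p, name)) - math.log(1.3 * getattr(p, name))) ** 2 / s_log**2
        assert objective(p, data, spec, prior, ctx) == pytest.approx(expected, rel=1e-10)


class TestFitMap:
    def test_underdetermined_without_prior_rejected(self):
        times = [1.0, 2.0]
        ctx = StubContext(times)
        data = _records(times, [1.0, 0.5])
        with pytest.raises(FitInputError):
            fit_map(data, ErrorModelSpec.uniform("data_based", "two_b", 0.2), None, FitParameters.default(), ctx)

    def test_recovers_stub_model_parameters(self):
        times = np.linspace(0.5, 20, 12)
        truth = FitParameters.default().to_array()
        truth[0], truth[1] = 5.0, 8.0
        ctx = StubContext(times)
        f = truth[0] * np.exp(-truth[1] / 10.0 * times)
        data = _records(times, f)
        prior = _uniform_prior(cv=1.0)
        init = FitParameters.default()
        res = fit_map(data, ErrorModelSpec.uniform("data_based", "two_b", 0.1), prior, init, ctx)
        assert res.converged
        assert res.estimates.to_array()[0] == pytest.approx(5.0, rel=2e-2)
        assert res.estimates.to_array()[1] == pytest.approx(8.0, rel=2e-2)

    def test_delta_prior_pins_parameter(self):
        times = np.linspace(0.5, 20, 12)
        ctx = StubContext(times)
        data = _records(times, 5.0 * np.exp(-0.8 * times))
        prior = _uniform_prior(cv=0.5)
        pinned_value = 0.00321
        prior.sd["sorting_rate"] = 0.0
        prior.mean["sorting_rate"] = pinned_value
        res = fit_map(data, ErrorModelSpec.uniform("data_based", "two_b", 0.1), prior, FitParameters.default(), ctx)
        assert res.estimates.sorting_rate == pytest.approx(pinned_value, rel=1e-3)
        assert res.cv_percent["sorting_rate"] == 0.0

    def test_trace_is_monotone_decreasing(self):
        times = np.linspace(0.5, 20, 12)
        ctx = StubContext(times)
        data = _records(times, 5.0 * np.exp(-0.8 * times) * 1.07)
        prior = _uniform_prior(cv=1.0)
        res = fit_map(data, ErrorModelSpec.uniform("data_based", "two_b", 0.1), prior, FitParameters.default(), ctx)
        assert all(b < a for a, b in zip(res.trace, res.trace[1:]))

    def test_record_order_permutation_leaves_optimum_unchanged(self):
        times = np.linspace(0.5, 20, 8)
        rng = np.random.default_rng(5)
        y = 5.0 * np.exp(-0.8 * times) * (1 + 0.1 * rng.standard_normal(8))
        spec = ErrorModelSpec(
            "data_based", "four_b", 0.0,
            {"D_organ": 0.1, "D_tumour": 0.2, "T_organ": 0.3, "T_tumour": 0.4},
        )
        prior = _uniform_prior(cv=1.0)
        res1 = fit_map(_records(times, y), spec, prior, FitParameters.default(), StubContext(times))
        perm = rng.permutation(8)
        res2 = fit_map(_records(times[perm], y[perm]), spec, prior, FitParameters.default(), StubContext(times[perm]))
        assert res1.estimates.to_array() == pytest.approx(res2.estimates.to_array(), rel=1e-9)

    def test_aic_counts_free_parameters(self):
        times = np.linspace(0.5, 20, 12)
        ctx = StubContext(times)
        data = _records(times, 5.0 * np.exp(-0.8 * times))
        prior = _uniform_prior(cv=0.5)
        res = fit_map(data, ErrorModelSpec.uniform("data_based", "two_b", 0.1), prior, FitParameters.default(), ctx)
        assert res.aic == pytest.approx(2 * res.n_free_parameters + res.objective_value)


class TestPbpkFits:
    def test_noise_free_full_design_recovery(self, noisefree_patient, noisefree_recovery_fit):
        """All 41 noise-free records, no prior: truth recovered within 10%."""
        truth = noisefree_patient.true_parameters.to_dict()
        est = noisefree_recovery_fit.estimates.to_dict()
        for name in PARAMETER_NAMES:
            assert est[name] == pytest.approx(truth[name], rel=0.10), name

    def test_diagnostic_fit_beats_truth_objective(self, noisefree_patient, constants):
        """8 diagnostic points + truth-centred prior: optimizer sanity."""
        diag = noisefree_patient.measurements.subset(phase="diagnostic")
        truth = noisefree_patient.true_parameters
        prior = BayesPrior(
            mean=truth.to_dict(),
            sd={k: 0.3 * v for k, v in truth.to_dict().items()},
        )
        ctx = PatientModelContext(noisefree_patient.physiology, constants, noisefree_patient.dosing)
        spec = ErrorModelSpec.uniform("data_based", "four_b", 0.2)
        res = fit_map(diag, spec, prior, truth, ctx, FitOptions())
        assert res.converged
        assert res.objective_value <= objective(truth, diag, spec, prior, ctx) + 1e-6


class TestGoodnessOfFit:
    def _result(self, cv, corr):
        return FitResult(
            estimates=FitParameters.default(),
            objective_value=0.0,
            cv_percent={n: cv for n in PARAMETER_NAMES},
            correlation=corr,
            aic=12.0,
            converged=True,
            residuals=pd.DataFrame(),
        )

    def test_identity_correlation_unflagged(self):
        rep = goodness_of_fit(self._result(10.0, np.eye(10)))
        assert rep.acceptable and rep.aic == 12.0

    def test_high_correlation_pair_named(self):
        corr = np.eye(10)
        corr[0, 3] = corr[3, 0] = 0.95
        rep = goodness_of_fit(self._result(10.0, corr))
        assert rep.correlation_flags == [("rd_tumour1", "rd_liver", 0.95)]

    def test_high_cv_flagged(self):
        rep = goodness_of_fit(self._result(60.0, np.eye(10)))
        assert set(rep.cv_flags) == set(PARAMETER_NAMES)

    def test_cv_from_quadratic_curvature_closed_form(self):
        """OF(z) = (z - z0)^2 / s^2 has curvature 2/s^2 and parameter sd s."""
        s = 0.17
        hessian = np.array([[2.0 / s**2]])
        cov = covariance_from_curvature(hessian)
        assert math.sqrt(cov[0, 0]) == pytest.approx(2.0 * s**2 / 2.0 / s, rel=1e-12)
        assert math.sqrt(cov[0, 0]) == pytest.approx(s, rel=1e-8)
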