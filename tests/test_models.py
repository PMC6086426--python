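"""Mean functions, likelihoods, and maximum-likelihood fitting."""

import numpy as np
import pytest
from scipy import stats

from ecothresh.community import ResponseSeries
from ecothresh.models import (
    FitConfig,
    ModelParams,
    fit,
    mean_bell,
    mean_linear,
    mean_logistic,
    mean_null,
    model_mean,
    n_params,
    negloglik,
)

X10 = np.arange(5.0, 60.0, 5.0)[:10]  # hypothetical 10-landscape gradient


def _series(y, family="normal", x=None):
    x = X10 if x is None else np.asarray(x, float)
    return ResponseSeries("gamma", "forest", "FS", x, y, family,
                          [f"L{i}" for i in range(len(x))])


class TestMeanFunctions:
    def test_null_is_constant(self):
        p = ModelParams("NULL", {"m": 3.2})
        assert mean_null(5.0, p) == 3.2
        assert mean_null(55.0, p) == 3.2

    def test_linear_and_nesting(self):
        p = ModelParams("GLM", {"intercept": 0.0, "slope": 1.0})
        assert mean_linear(25.0, p) == 25.0
        flat = ModelParams("GLM", {"intercept": 3.2, "slope": 0.0})
        np.testing.assert_allclose(
            mean_linear(X10, flat), mean_null(X10, ModelParams("NULL", {"m": 3.2}))
        )

    def test_logistic_midpoint_and_asymptotes(self):
        p = ModelParams("LOG", {"a": 10.0, "b": 25.0, "c": 3.0, "d": 2.0})
        assert mean_logistic(25.0, p) == pytest.approx(7.0)  # d + a/2
        assert mean_logistic(1000.0, p) == pytest.approx(12.0)  # d + a
        assert mean_logistic(-1000.0, p) == pytest.approx(2.0)  # d

    def test_logistic_overflow_safe(self):
        p = ModelParams("LOG", {"a": 10.0, "b": 25.0, "c": 3.0, "d": 2.0})
        vals = mean_logistic(np.array([-1e6, 1e6]), p)
        assert np.all(np.isfinite(vals))

    def test_bell_peak_symmetry_and_tails(self):
        p = ModelParams("BELL", {"a": 5.0, "b": 0.1, "c": 1.0, "d": 20.0})
        assert mean_bell(20.0, p) == pytest.approx(6.0)  # a + c at the peak
        assert mean_bell(27.0, p) == pytest.approx(mean_bell(13.0, p))
        assert mean_bell(1e4, p) == pytest.approx(1.0)


class TestNegloglik:
    def test_poisson_matches_logpmf_sum(self):
        y = np.array([2.0, 2.0, 2.0])
        s = _series(y, family="poisson", x=[5, 10, 15])
        p = ModelParams("NULL", {"m": y.mean()})
        expected = -stats.poisson.logpmf(y, y.mean()).sum()
        assert negloglik(s, "NULL", p) == pytest.approx(expected, rel=1e-12)

    def test_normal_zero_residuals(self):
        y = np.linspace(1, 4, 10)
        s = _series(y)
        p = ModelParams("GLM", {"intercept": 1.0, "slope": (4 - 1) / (X10[-1] - X10[0])},
                        sigma=1.0)
        p.values["intercept"] = 1.0 - p.values["slope"] * X10[0]
        assert negloglik(s, "GLM", p) == pytest.approx(0.5 * 10 * np.log(2 * np.pi))

    def test_degenerate_logistic_equals_null(self):
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0])
        s = _series(y)
        log = ModelParams("LOG", {"a": 0.0, "b": 25.0, "c": 3.0, "d": 4.2}, sigma=1.3)
        null = ModelParams("NULL", {"m": 4.2}, sigma=1.3)
        assert negloglik(s, "LOG", log) == pytest.approx(negloglik(s, "NULL", null))

    def test_nonfinite_mean_penalized_not_nan(self):
        s = _series(np.ones(10), family="poisson")
        p = ModelParams("GLM", {"intercept": np.inf, "slope": 0.0})
        val = negloglik(s, "GLM", p)
        assert np.isfinite(val) and val >= 1e9


class TestFit:
    def test_poisson_null_mle_is_sample_mean(self):
        y = np.array([4, 0, 3, 7, 2, 5, 1, 6, 3, 2], dtype=float)
        s = _series(y, family="poisson")
        res = fit(s, "NULL", FitConfig(n_restarts=3, seed=0))
        assert res.converged
        assert res.params.values["m"] == pytest.approx(y.mean(), abs=1e-6)

    def test_normal_glm_mle_matches_ols(self):
        rng = np.random.default_rng(1)
        y = 2.0 + 0.3 * X10 + rng.normal(0, 0.7, 10)
        s = _series(y)
        res = fit(s, "GLM", FitConfig(n_restarts=3, seed=0))
        slope, intercept = np.polyfit(X10, y, 1)
        assert res.params.values["slope"] == pytest.approx(slope, abs=1e-5)
        assert res.params.values["intercept"] == pytest.approx(intercept, abs=1e-4)
        resid = y - (intercept + slope * X10)
        assert res.params.sigma**2 == pytest.approx(np.mean(resid**2), rel=1e-4)

    def test_noiseless_linear_recovery(self):
        y = 1.5 + 0.2 * X10
        res = fit(_series(y), "GLM", FitConfig(n_restarts=3, seed=0))
        assert res.params.values["slope"] == pytest.approx(0.2, abs=1e-6)
        assert res.params.values["intercept"] == pytest.approx(1.5, abs=1e-6)

    def test_nested_models_cannot_fit_worse(self, fast_fit):
        rng = np.random.default_rng(4)
        y = np.round(np.clip(3 + 0.1 * X10 + rng.normal(0, 1, 10), 0, None))
        for family in ("normal", "poisson"):
            s = _series(y, family=family)
            lls = {m: fit(s, m, fast_fit).loglik for m in ("NULL", "GLM", "LOG", "BELL")}
            assert lls["NULL"] <= lls["GLM"] + 1e-6
            assert lls["NULL"] <= lls["LOG"] + 1e-6
            assert lls["NULL"] <= lls["BELL"] + 1e-6

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(9)
        y = 5 + 3 / (1 + np.exp((25 - X10) / 4)) + rng.normal(0, 0.3, 10)
        cfg = FitConfig(n_restarts=8, seed=123)
        a = fit(_series(y), "LOG", cfg)
        b = fit(_series(y), "LOG", cfg)
        assert a.loglik == b.loglik
        assert a.params.values == b.params.values

    def test_location_equivariance_in_x(self, fast_fit):
        rng = np.random.default_rng(12)
        y = 2 + 8 / (1 + np.exp((25 - X10) / 3)) + rng.normal(0, 0.3, 10)
        shift = 100.0
        res0 = fit(_series(y), "LOG", fast_fit)
        res1 = fit(_series(y, x=X10 + shift), "LOG", fast_fit)
        assert res1.params.values["b"] - res0.params.values["b"] == pytest.approx(
            shift, abs=0.5
        )
        assert res1.loglik == pytest.approx(res0.loglik, abs=1e-3)

    def test_logistic_midpoint_recovery_monte_carlo(self, fast_fit):
        """Over replicates of logistic-decline data, the fitted midpoint b
        is centred on its generating value."""
        truth = ModelParams("LOG", {"a": 8.0, "b": 25.0, "c": 3.0, "d": 1.0})
        rng = np.random.default_rng(77)
        bs = []
        for _ in range(150):
            y = model_mean(X10, truth) + rng.normal(0, 0.5, 10)
            res = fit(_series(y), "LOG", FitConfig(n_restarts=4, seed=0))
            if res.converged and abs(res.params.values["b"] - 25) < 25:
                bs.append(res.params.values["b"])
        bs = np.array(bs)
        assert len(bs) > 100
        mc_half = 1.96 * bs.std() / np.sqrt(len(bs))
        assert abs(bs.mean() - 25.0) < max(mc_half, 0.5)

    def test_too_few_observations_flagged(self):
        s = _series(np.array([1.0, 2.0, 3.0]), x=[5, 10, 15])
        res = fit(s, "LOG", FitConfig(n_restarts=2, seed=0))
        assert not res.converged
        assert "too few" in res.message

    def test_k_bookkeeping_modes(self):
        assert n_params("LOG", "normal", "conventional") == 4
        assert n_params("LOG", "normal", "strict") == 5
        assert n_params("LOG", "poisson", "strict") == 4
        assert n_params("NULL", "normal", "strict") == 2
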