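"""AICc ranking, Akaike weights, best-model sets, and diagnostics."""

import numpy as np
import pytest

from ecothresh.community import ResponseSeries
from ecothresh.errors import InputError, NumericalError
from ecothresh.models import FitConfig, FitResult, ModelParams, fit
from ecothresh.selection import aicc, diagnose, dispersion_check, insufficiency_test, select

X10 = np.arange(5.0, 60.0, 5.0)[:10]


def _series(y, family="normal"):
    return ResponseSeries("gamma", "forest", "FS", X10, y, family,
                          [f"L{i}" for i in range(10)])


def _fit_with_aicc(model, target_aicc, K=2, n=10):
    """A synthetic converged FitResult whose AICc equals target_aicc."""
    loglik = -(target_aicc - 2 * K - 2 * K * (K + 1) / (n - K - 1)) / 2
    return FitResult(model, "normal", ModelParams("NULL", {"m": 0.0}, 1.0),
                     loglik, K, n, True)


class TestAicc:
    def test_closed_form_values(self):
        assert aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)
        assert aicc(0.0, 4, 10) == pytest.approx(16.0)

    def test_large_n_limit_is_plain_aic(self):
        assert aicc(-3.0, 3, 10**9) == pytest.approx(6 + 6, abs=1e-6)

    def test_undefined_when_n_too_small(self):
        assert np.isnan(aicc(0.0, 4, 5))


class TestSelect:
    def test_equal_aicc_splits_weights(self):
        sel = select([_fit_with_aicc("NULL", 10.0), _fit_with_aicc("GLM", 10.0, K=3)])
        assert sel.table["weight"].tolist() == pytest.approx([0.5, 0.5])
        assert set(sel.best_set) == {"NULL", "GLM"}

    def test_close_deltas_all_enter_best_set(self):
        # mirrors a three-way near-tie among linear, flat and logistic fits
        sel = select(
            [
                _fit_with_aicc("GLM", 10.0, K=3),
                _fit_with_aicc("NULL", 10.9, K=2),
                _fit_with_aicc("LOG", 11.1, K=4),
            ]
        )
        assert sel.best_set == ["GLM", "NULL", "LOG"]
        np.testing.assert_allclose(
            sel.table["delta_aicc"], [0.0, 0.9, 1.1], atol=1e-12
        )

    def test_large_delta_excluded_with_negligible_weight(self):
        sel = select([_fit_with_aicc("NULL", 10.0), _fit_with_aicc("LOG", 35.4, K=4)])
        assert sel.best_set == ["NULL"]
        w = dict(zip(sel.table["model"], sel.table["weight"]))
        assert w["NULL"] > 0.999 and w["LOG"] < 1e-5

    def test_weights_sum_to_one_and_shift_invariant(self):
        base = [10.0, 11.3, 14.0, 22.0]
        for shift in (0.0, 137.0):
            sel = select([_fit_with_aicc(m, a + shift)
                          for m, a in zip(("NULL", "GLM", "LOG", "BELL"), base)])
            assert sel.table["weight"].sum() == pytest.approx(1.0, abs=1e-9)
            if shift == 0.0:
                ref = sel.table["weight"].tolist()
        assert sel.table["weight"].tolist() == pytest.approx(ref)

    def test_equal_k_ranking_matches_loglik(self, fast_fit):
        rng = np.random.default_rng(6)
        y = 3 + 0.15 * X10 + rng.normal(0, 0.5, 10)
        s = _series(y)
        f_log = fit(s, "LOG", fast_fit)
        f_bell = fit(s, "BELL", fast_fit)
        sel = select([f_log, f_bell])
        best_by_ll = max((f_log, f_bell), key=lambda f: f.loglik).model
        assert sel.best_model == best_by_ll

    def test_sorted_and_unique_zero_delta(self):
        sel = select([_fit_with_aicc(m, a) for m, a in
                      [("NULL", 12.0), ("GLM", 10.0), ("LOG", 17.0)]])
        deltas = sel.table["delta_aicc"].to_numpy()
        assert (np.diff(deltas) >= 0).all()
        assert (deltas == 0).sum() == 1

    def test_nothing_converged_is_an_error(self):
        bad = FitResult("NULL", "normal", None, -np.inf, 2, 10, False)
        with pytest.raises(NumericalError):
            select([bad])


class TestDiagnostics:
    def test_linear_residuals_flag_insufficiency(self):
        y = 0.5 * X10  # NULL residuals are exactly proportional to x
        s = _series(y)
        f = fit(s, "NULL", FitConfig(n_restarts=2, seed=0))
        rep = insufficiency_test(s, f)
        assert rep.residual_cover_correlation == pytest.approx(1.0, abs=1e-9)
        assert rep.insufficient

    def test_perfect_fit_reports_undefined_correlation(self):
        y = 1.0 + 0.2 * X10
        s = _series(y)
        f = fit(s, "GLM", FitConfig(n_restarts=2, seed=0))
        rep = insufficiency_test(s, f)
        assert rep.correlation_undefined and not rep.insufficient

    def test_null_on_trending_data_usually_flagged(self):
        rng = np.random.default_rng(8)
        flagged = 0
        for _ in range(100):
            y = 2 + 0.25 * X10 + rng.normal(0, 1.0, 10)
            s = _series(y)
            f = fit(s, "NULL", FitConfig(n_restarts=2, seed=0))
            flagged += insufficiency_test(s, f).insufficient
        assert flagged >= 80

    def test_dispersion_zero_when_exact(self):
        y = np.full(10, 4.0)
        s = _series(y, family="poisson")
        f = fit(s, "NULL", FitConfig(n_restarts=2, seed=0))
        ratio, n_floored = dispersion_check(s, f)
        assert ratio == pytest.approx(0.0, abs=1e-8)
        assert n_floored == 0

    def test_dispersion_near_one_for_poisson_data(self):
        rng = np.random.default_rng(10)
        ratios = []
        for _ in range(200):
            y = rng.poisson(6.0, 10).astype(float)
            s = _series(y, family="poisson")
            f = fit(s, "NULL", FitConfig(n_restarts=2, seed=0))
            ratios.append(dispersion_check(s, f)[0])
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)

    def test_dispersion_detects_overdispersed_counts(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(100):
            lam = rng.gamma(shape=2.0, scale=3.0, size=10)  # NB-like mixing
            y = rng.poisson(lam).astype(float)
            s = _series(y, family="poisson")
            f = fit(s, "NULL", FitConfig(n_restarts=2, seed=0))
            hits += dispersion_check(s, f)[0] > 1.5
        assert hits >= 70

    def test_diagnose_family_specific_fields(self, fast_fit):
        rng = np.random.default_rng(13)
        y = rng.poisson(5.0, 10).astype(float)
        s = _series(y, family="poisson")
        rep = diagnose(s, fit(s, "NULL", fast_fit))
        assert rep.overdispersion_ratio is not None and rep.shapiro_p is None
        yn = 4 + rng.normal(0, 1, 10)
        sn = _series(yn)
        repn = diagnose(sn, fit(sn, "NULL", fast_fit))
        assert repn.shapiro_p is not None and repn.overdispersion_ratio is None

    def test_dispersion_requires_poisson_family(self, fast_fit):
        s = _series(np.ones(10) * 2.5)
        with pytest.raises(InputError):
            dispersion_check(s, fit(s, "NULL", fast_fit))


class TestSelectionConsistency:
    def test_strong_linear_signal_beats_null(self):
        """With |slope|*range(x) > 5 sigma the flat model should almost
        never outrank the trend models."""
        rng = np.random.default_rng(21)
        cfg = FitConfig(n_restarts=4, seed=0)
        wins = 0
        n_rep = 500
        for _ in range(n_rep):
            y = 1.0 + 0.12 * X10 + rng.normal(0, 1.0, 10)
            s = _series(y)
            fits = [fit(s, m, cfg) for m in ("NULL", "GLM", "LOG")]
            sel = select(fits)
            ranks = {m: i for i, m in enumerate(sel.table["model"])}
            wins += min(ranks["GLM"], ranks["LOG"]) < ranks["NULL"]
        assert wins / n_rep >= 0.95
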