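"""Polynomial, piecewise and spatial-GLS fitting, selection, and bands."""

import numpy as np
import pytest
from scipy import stats

from lineagediv.regression import (STRUCTURES, SpatialCorrelation, correlation_matrix,
                                   evaluate_piecewise, fit_piecewise, fit_polynomial,
                                   gls_fit, mean_ci, select_model)
from lineagediv.simulate import distance_matrix_km


class TestPolynomial:
    def test_exact_line(self):
        x = np.linspace(0, 10, 20)
        y = 2.5 * x - 1.0
        f = fit_polynomial(x, y, 1)
        assert f.coefficients == pytest.approx([-1.0, 2.5], abs=1e-10)
        assert f.r2 == pytest.approx(1.0)

    def test_quadratic_beats_linear_on_curved_truth(self):
        rng = np.random.default_rng(1)
        x = np.linspace(0, 10, 60)
        y = (x - 5.0) ** 2 + rng.normal(0, 0.5, 60)
        assert fit_polynomial(x, y, 2).aic < fit_polynomial(x, y, 1).aic

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 5, 10)
        y = rng.normal(size=10)
        f = fit_polynomial(x, y, 2)
        X = np.vander(x, 3, increasing=True)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert f.coefficients == pytest.approx(beta, abs=1e-10)

    def test_rank_deficient(self):
        with pytest.raises(ValueError):
            fit_polynomial(np.ones(10), np.arange(10.0), 1)


class TestPiecewise:
    def test_noiseless_recovery(self):
        x = np.concatenate([np.linspace(0, 10, 30), np.linspace(10.5, 20, 30)])
        bp_true = x[30]
        y = np.where(x < bp_true, 2.0 * x + 1.0, -1.0 * x + 40.0)
        f = fit_piecewise(x, y, min_segment=5)
        assert f.break_point == pytest.approx(bp_true)
        lo, hi = f.coefficients
        assert (lo.slope, lo.intercept) == pytest.approx((2.0, 1.0), abs=1e-10)
        assert (hi.slope, hi.intercept) == pytest.approx((-1.0, 40.0), abs=1e-10)

    def test_chosen_bp_minimizes_rss_exhaustively(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 100, 50)
        y = np.where(x < 40, 0.5 * x, -0.2 * x + 30) + rng.normal(0, 2, 50)
        f = fit_piecewise(x, y, min_segment=5)

        def rss_at(c):
            left = x < c
            out = 0.0
            for m in (left, ~left):
                X = np.column_stack([np.ones(m.sum()), x[m]])
                beta, res, *_ = np.linalg.lstsq(X, y[m], rcond=None)
                out += float(((y[m] - X @ beta) ** 2).sum())
            return out

        best = min(rss_at(c) for c in np.unique(x)
                   if (x < c).sum() >= 5 and (x >= c).sum() >= 5)
        assert rss_at(f.break_point) == pytest.approx(best, rel=1e-9)

    def test_piecewise_rss_below_linear(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 50, 80)
        y = rng.normal(size=80)
        fp = fit_piecewise(x, y, min_segment=5)
        fl = fit_polynomial(x, y, 1)
        rss_p = float(((fp.fitted - y) ** 2).sum())
        rss_l = float(((fl.fitted - y) ** 2).sum())
        assert rss_p <= rss_l + 1e-9

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_piecewise(np.arange(8.0), np.arange(8.0), min_segment=5)


class TestEvaluatePiecewise:
    @pytest.fixture
    def reference_fit(self):
        """Segments with the reference coefficients around a 1,490 mm break."""
        x = np.concatenate([np.linspace(300, 1489, 50), np.linspace(1490, 3500, 50)])
        y = np.where(x < 1490, 0.002326 * x - 2.634307, -0.0006 * x + 0.711)
        return fit_piecewise(x, y, min_segment=5)

    def test_before_segment_value(self, reference_fit):
        assert evaluate_piecewise(reference_fit, 1000.0) == pytest.approx(-0.308307, abs=1e-6)

    def test_after_segment_value(self, reference_fit):
        assert evaluate_piecewise(reference_fit, 1490.0) == pytest.approx(-0.183, abs=1e-6)

    def test_constant_segment(self):
        x = np.concatenate([np.linspace(0, 9, 20), np.linspace(10, 20, 20)])
        y = np.where(x < 10, 3.0, 3.0)
        f = fit_piecewise(x, y, min_segment=5)
        assert evaluate_piecewise(f, 7.3) == pytest.approx(3.0, abs=1e-9)


class TestGLS:
    def test_none_equals_ols(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 40)
        y = 1.5 * x + rng.normal(0, 1, 40)
        coords = np.column_stack([rng.uniform(-60, -50, 40), rng.uniform(-10, 0, 40)])
        X = np.column_stack([np.ones(40), x])
        f = gls_fit(X, y, coords, "none")
        beta_ols = np.linalg.solve(X.T @ X, X.T @ y)
        assert f.coefficients == pytest.approx(beta_ols, abs=1e-10)
        assert f.delta_aic_vs_null_spatial == pytest.approx(0.0)

    def test_fixed_range_matches_closed_form(self):
        """5-point toy: beta-hat equals (X'S^-1X)^-1 X'S^-1 y with hand-built S."""
        lon = np.array([-60.0, -59.0, -58.0, -57.0, -56.0])
        lat = np.array([-10.0, -9.5, -9.0, -8.5, -8.0])
        x = np.array([500.0, 1000.0, 1500.0, 2000.0, 2500.0])
        y = np.array([-1.0, 0.2, 0.8, 0.5, -0.3])
        X = np.column_stack([np.ones(5), x])
        spec = SpatialCorrelation("exponential", range_km=150.0)
        f = gls_fit(X, y, np.column_stack([lon, lat]), spec)
        d = distance_matrix_km(lon, lat)
        S = np.exp(-d / 150.0)
        Si = np.linalg.inv(S)
        beta = np.linalg.solve(X.T @ Si @ X, X.T @ Si @ y)
        assert f.coefficients == pytest.approx(beta, abs=1e-8)

    def test_correlation_functions_basic_shape(self):
        d = np.linspace(0, 1000, 200)
        for st in STRUCTURES[1:]:
            spec = SpatialCorrelation(st, range_km=300.0)
            rho = correlation_matrix(np.abs(d[:, None] - d[None, :]), spec)
            assert rho[0, 0] == pytest.approx(1.0)
            first_row = rho[0]
            assert (np.diff(first_row) <= 1e-12).all()

    def test_profile_ml_beats_random_ranges(self):
        rng = np.random.default_rng(6)
        lon = rng.uniform(-60, -50, 60)
        lat = rng.uniform(-10, 0, 60)
        d = distance_matrix_km(lon, lat)
        x = rng.uniform(0, 10, 60)
        y = x * 0.3 + np.linalg.cholesky(np.exp(-d / 300) + 1e-10 * np.eye(60)) @ rng.normal(0, 1, 60)
        X = np.column_stack([np.ones(60), x])
        f = gls_fit(X, y, np.column_stack([lon, lat]), "exponential")
        for r in rng.uniform(1, 2 * d.max(), 10):
            fr = gls_fit(X, y, np.column_stack([lon, lat]),
                         SpatialCorrelation("exponential", range_km=float(r)))
            assert f.loglik >= fr.loglik - 1e-6

    def test_range_recovery_and_aic_preference(self):
        hits = 0
        beats = 0
        n = 100
        for s in range(10):
            rng = np.random.default_rng(700 + s)
            lon = rng.uniform(-70, -40, n)
            lat = rng.uniform(-20, 5, n)
            d = distance_matrix_km(lon, lat)
            x = rng.uniform(300, 3500, n)
            noise = np.linalg.cholesky(np.exp(-d / 200.0) + 1e-10 * np.eye(n)) @ rng.normal(0, 0.5, n)
            y = 0.001 * x + noise
            X = np.column_stack([np.ones(n), x])
            f = gls_fit(X, y, np.column_stack([lon, lat]), "exponential")
            if 100.0 <= f.spatial.range_km <= 400.0:
                hits += 1
            if f.delta_aic_vs_null_spatial < 0:
                beats += 1
        assert hits >= 7
        assert beats >= 9

    def test_all_zero_distances(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        coords = np.zeros((10, 2))
        with pytest.raises(ValueError, match="distance"):
            gls_fit(X, np.arange(10.0), coords, "exponential")


class TestSelectModel:
    def _fit(self, aic, k, y):
        from lineagediv.regression import ModelFit
        return ModelFit(kind=f"m{k}", coefficients=np.zeros(1), k=k, loglik=0.0,
                        aic=aic, r2=0.5, adj_r2=0.5, n=len(y), _y=y)

    def test_minimum_aic(self):
        y = np.arange(5.0)
        fits = [self._fit(a, 3, y) for a in (100.0, 90.0, 95.0)]
        assert select_model(fits).aic == 90.0

    def test_tie_breaks_to_fewer_params(self):
        y = np.arange(5.0)
        linear = self._fit(50.0, 3, y)
        piecewise = self._fit(50.0, 6, y)
        assert select_model([piecewise, linear]) is linear

    def test_different_responses_rejected(self):
        with pytest.raises(ValueError):
            select_model([self._fit(1.0, 3, np.arange(5.0)),
                          self._fit(2.0, 3, np.arange(6.0))])


class TestMeanCI:
    def test_band_nesting(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 10, 50)
        y = x + rng.normal(0, 1, 50)
        f = fit_polynomial(x, y, 1)
        g = np.linspace(0, 10, 25)
        b99 = mean_ci(f, g, 0.99)
        b95 = mean_ci(f, g, 0.95)
        assert (b99["lower"] <= b95["lower"] + 1e-12).all()
        assert (b99["upper"] >= b95["upper"] - 1e-12).all()

    def test_half_width_at_mean_x(self):
        """Classic t * s / sqrt(n) at the design centre."""
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 10, 40)
        y = 2.0 * x + rng.normal(0, 1.3, 40)
        f = fit_polynomial(x, y, 1)
        band = mean_ci(f, np.array([x.mean()]), 0.95)
        resid = y - f.fitted
        s = np.sqrt(resid @ resid / (40 - 2))
        t = stats.t.ppf(0.975, 38)
        expected = t * s / np.sqrt(40)
        half = float(band["upper"][0] - band["fit"][0])
        assert half == pytest.approx(expected, rel=1e-9)

    def test_zero_noise_zero_width(self):
        x = np.linspace(0, 10, 30)
        f = fit_polynomial(x, 3.0 * x + 1.0, 1)
        band = mean_ci(f, x, 0.99)
        assert np.allclose(band["upper"] - band["lower"], 0.0, atol=1e-8)

    def test_piecewise_band(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(0, 100, 80)
        y = np.where(x < 50, x, 100 - x) + rng.normal(0, 1, 80)
        f = fit_piecewise(x, y, min_segment=5)
        band = mean_ci(f, np.linspace(0, 100, 40), 0.99)
        assert (band["upper"] > band["lower"]).all()

    def test_bad_level(self):
        f = fit_polynomial(np.arange(10.0), np.arange(10.0), 1)
        with pytest.raises(ValueError):
            mean_ci(f, np.arange(5.0), 1.5)
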