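import math

import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone

from trendpower import (
    RatioSeries,
    Scenario,
    TrendPrior,
    TrendRegressor,
    fit_cauchy_prior,
    fit_normal_prior,
    fit_trend,
    fit_unregularized,
    is_significant,
    simulate_series,
    weakly_informative_prior,
)

from conftest import profile_objective, random_ratio_series


class TestUnregularized:
    def test_closed_form_three_point_example(self, hand_series):
        fit = fit_unregularized(hand_series, alpha=0.05)
        assert fit.beta_hat == pytest.approx(-0.48, abs=1e-12)
        assert fit.r_hat == pytest.approx(0.61878, abs=1e-5)
        assert fit.se == pytest.approx(0.028284271, abs=1e-8)
        assert fit.df == 2
        assert fit.p_value == pytest.approx(0.0034542, abs=1e-6)

    def test_noiseless_series_is_exact_and_degenerate(self, rng):
        sc = Scenario(T=5, r=0.5, cv_lower=0.0, cv_upper=0.0)
        fit = fit_unregularized(simulate_series(sc, rng))
        assert fit.beta_hat == pytest.approx(math.log(0.5), abs=1e-14)
        assert fit.degenerate
        assert fit.p_value == 0.0
        assert fit.se == 0.0

    def test_flat_series_estimates_no_trend(self):
        series = RatioSeries(x=np.linspace(0, 1, 6), log_ratio=np.zeros(6))
        fit = fit_unregularized(series)
        assert fit.beta_hat == 0.0
        assert fit.r_hat == 1.0

    def test_matches_closed_form_on_random_series(self, rng):
        for _ in range(50):
            series = random_ratio_series(rng)
            fit = fit_unregularized(series)
            x, y = series.x, series.log_ratio
            assert fit.beta_hat == pytest.approx((x @ y) / (x @ x), rel=1e-12)

    def test_p_value_from_independent_t_cdf(self, hand_series):
        fit = fit_unregularized(hand_series)
        t = abs(fit.beta_hat) / fit.se
        assert fit.p_value == pytest.approx(2 * (1 - stats.t.cdf(t, fit.df)), rel=1e-12)


class TestRegularized:
    def test_huge_prior_scale_recovers_ml(self, hand_series):
        ml = fit_unregularized(hand_series)
        for family in ("normal", "cauchy"):
            prior = TrendPrior(family=family, scale=1e8)
            fit = fit_trend(hand_series, family, prior_scale=1e8)
            assert fit.beta_hat == pytest.approx(ml.beta_hat, abs=1e-6)
            assert fit.se == pytest.approx(ml.se, abs=1e-6)

    def test_tiny_normal_scale_shrinks_to_zero(self, hand_series):
        prior = TrendPrior(family="normal", scale=1e-8)
        fit = fit_normal_prior(hand_series, prior)
        assert abs(fit.beta_hat) < 1e-10

    def test_normal_ridge_matches_grid_search(self, hand_series):
        prior = TrendPrior(family="normal", scale=math.log(2) / 2)
        fit = fit_normal_prior(hand_series, prior)
        grid = np.arange(-1, 1, 1e-5)
        obj = profile_objective(hand_series, lambda b: b**2 / (2 * prior.scale**2), grid)
        assert fit.beta_hat == pytest.approx(grid[obj.argmax()], abs=1e-4)
        assert abs(fit.beta_hat) < 0.48  # shrunk toward 0 relative to the ML -0.48

    def test_cauchy_map_matches_grid_search(self, hand_series):
        prior = weakly_informative_prior(0.025)
        fit = fit_cauchy_prior(hand_series, prior, em_variant="map")
        grid = np.arange(-1, 1, 1e-5)
        obj = profile_objective(
            hand_series, lambda b: np.log1p((b / prior.scale) ** 2), grid
        )
        assert fit.beta_hat == pytest.approx(grid[obj.argmax()], abs=1e-4)

    def test_em_fixed_points_solve_penalized_score_equation(self, rng):
        """Both EM variants' map fixed point and the normal ridge satisfy the
        exact stationarity condition of their penalized objectives, and agree
        with a local brute-force grid search (the posterior can be bimodal
        under the heavy-tailed prior; the EM tracks the data-side mode)."""
        prior_c = weakly_informative_prior(0.025)
        prior_n = TrendPrior(family="normal", scale=math.log(2) / 2)
        for _ in range(100):
            series = random_ratio_series(rng, sd=0.2, slope_range=0.8)
            x, y = series.x, series.log_ratio
            sxx, sxy = x @ x, x @ y
            for fit, dpen in [
                (
                    fit_normal_prior(series, prior_n),
                    lambda b: b / prior_n.scale**2,
                ),
                (
                    fit_cauchy_prior(series, prior_c, em_variant="map"),
                    lambda b: 2 * b / (prior_c.scale**2 + b * b),
                ),
            ]:
                if fit.degenerate or not fit.converged:
                    continue
                b = fit.beta_hat
                rss = float(((y - b * x) ** 2).sum())
                sigma2 = rss / (series.T - 1)
                score = (sxy - b * sxx) / sigma2 - dpen(b)
                assert abs(score) < 1e-4 / max(sigma2, 1e-3)
                # local grid search around the fixed point
                grid = np.arange(b - 0.05, b + 0.05, 1e-5)
                pen = (
                    (lambda g: g**2 / (2 * prior_n.scale**2))
                    if fit.prior.family == "normal"
                    else (lambda g: np.log1p((g / prior_c.scale) ** 2))
                )
                obj = profile_objective(series, pen, grid)
                assert b == pytest.approx(grid[obj.argmax()], abs=1e-4)

    def test_shrinkage_never_exceeds_ml_magnitude(self, rng):
        for _ in range(200):
            series = random_ratio_series(rng)
            ml = abs(fit_unregularized(series).beta_hat)
            for approach in ("normal", "cauchy"):
                for variant in ("map", "with_variance"):
                    fit = fit_trend(series, approach, em_variant=variant)
                    assert abs(fit.beta_hat) <= ml + 1e-10

    def test_estimate_monotone_in_normal_prior_scale(self, rng):
        for _ in range(20):
            series = random_ratio_series(rng)
            scales = np.logspace(-4, 4, 25)
            betas = [
                abs(
                    fit_normal_prior(
                        series, TrendPrior(family="normal", scale=s)
                    ).beta_hat
                )
                for s in scales
            ]
            assert all(b2 >= b1 - 1e-9 for b1, b2 in zip(betas, betas[1:]))
            assert betas[0] < 1e-6  # total shrinkage
            ml = abs(fit_unregularized(series).beta_hat)
            assert betas[-1] == pytest.approx(ml, abs=1e-6)

    def test_flat_series_is_symmetric_fixed_point(self):
        series = RatioSeries(x=np.linspace(0, 1, 5), log_ratio=np.zeros(5))
        fit = fit_cauchy_prior(series)
        assert fit.beta_hat == 0.0


class TestSignificance:
    def test_strict_inequality_convention(self, hand_series):
        fit = fit_unregularized(hand_series)
        assert is_significant(fit, 0.05)
        import dataclasses

        exactly = dataclasses.replace(fit, p_value=0.05)
        assert not is_significant(exactly, 0.05)
        assert is_significant(dataclasses.replace(fit, p_value=0.19), 0.20)

    def test_ci_excludes_zero_iff_significant_unregularized(self, rng):
        for alpha in (0.05, 0.20):
            for _ in range(100):
                series = random_ratio_series(rng)
                fit = fit_trend(series, "unregularized", alpha)
                excludes = fit.ci_beta[0] > 0 or fit.ci_beta[1] < 0
                assert excludes == is_significant(fit, alpha)

    def test_ci_transforms_to_r_scale(self, hand_series):
        fit = fit_unregularized(hand_series, alpha=0.05)
        assert fit.ci_r[0] == pytest.approx(math.exp(fit.ci_beta[0]))
        assert fit.ci_r[1] == pytest.approx(math.exp(fit.ci_beta[1]))
        assert fit.ci_beta[0] < fit.beta_hat < fit.ci_beta[1]


class TestEstimatorApi:
    def test_sklearn_contract(self, hand_series):
        est = TrendRegressor(prior="cauchy", xi=0.05, alpha=0.2)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.set_params(alpha=0.05)
        assert est.alpha == 0.05

    def test_fit_predict_roundtrip(self, hand_series):
        X = hand_series.x.reshape(-1, 1)
        est = TrendRegressor().fit(X, hand_series.log_ratio)
        pred = est.predict(X)
        assert pred == pytest.approx(est.coef_[0] * hand_series.x)
        assert est.r_hat_ == pytest.approx(math.exp(est.coef_[0]))

    def test_rejects_invalid_inputs(self, hand_series):
        with pytest.raises(ValueError):
            TrendRegressor().fit(np.array([[0.0], [1.0]]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            TrendRegressor().fit(np.zeros((4, 2)), np.zeros(4))
        with pytest.raises(ValueError):
            TrendRegressor(alpha=1.5).fit(
                hand_series.x.reshape(-1, 1), hand_series.log_ratio
            )
        with pytest.raises(ValueError):
            fit_trend(hand_series, "lasso")
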