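import numpy as np
import pytest

from trendpower import RatioSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def hand_series():
    """Three-point series with a known closed-form through-origin fit."""
    return RatioSeries(x=np.array([0.0, 0.5, 1.0]), log_ratio=np.array([0.0, -0.2, -0.5]))


def random_ratio_series(rng, T=None, sd=0.3, slope_range=1.0):
    """Random small series for property tests (valid RatioSeries)."""
    T = T if T is not None else int(rng.integers(3, 12))
    x = np.sort(rng.uniform(0.01, 0.99, size=T - 2))
    x = np.concatenate([[0.0], x, [1.0]])
    beta = rng.uniform(-slope_range, slope_range)
    y = beta * x + rng.normal(0.0, sd, size=T)
    y[0] = 0.0
    return RatioSeries(x=x, log_ratio=y)


def profile_objective(series, penalty, beta_grid):
    """Profile log-posterior on a beta grid: -(T-1)/2 log RSS(b) - penalty(b).

    Stationary points of this objective satisfy the penalized score equation
    sum(x(y-xb))/sigma2 = penalty'(b) with sigma2 = RSS(b)/(T-1), so it is the
    independent brute-force oracle for the ridge / EM fixed points.
    """
    x, y = series.x, series.log_ratio
    sxx, sxy, syy = x @ x, x @ y, y @ y
    rss = np.maximum(syy - 2.0 * beta_grid * sxy + beta_grid**2 * sxx, 1e-300)
    return -0.5 * (series.T - 1) * np.log(rss) - penalty(beta_grid)
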