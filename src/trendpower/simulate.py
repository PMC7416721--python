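"""Data-generating mechanism for abundance-estimate time series.

A monitored population declines geometrically over a study period of ``T``
evenly spaced sampling occasions, so that the fraction remaining at occasion
``t`` is ``p_t = r**((t - 1)/(T - 1))``: ``p_1 = 1`` at the baseline and
``p_T = r`` at the end.  Each occasion yields a lognormally distributed
abundance estimate whose coefficient of variation (CV) is itself drawn
uniformly between scenario bounds.  Analyses operate on the ratios of each
estimate to the first one, so the baseline abundance is a nuisance constant
that cancels out — but the baseline's own sampling noise propagates into
every ratio, which is what makes the null distribution of the trend test
non-standard.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Scenario",
    "RatioSeries",
    "ScenarioGridConfig",
    "true_proportion",
    "cv_to_sdlog",
    "simulate_series",
    "build_scenario_grid",
    "default_grid_config",
    "annual_rate_to_overall",
    "series_to_frame",
]


@dataclass(frozen=True)
class Scenario:
    """One cell of the factorial simulation design.

    Parameters
    ----------
    T : int
        Number of sampling occasions (study length), at least 3.
    r : float
        True fraction of the initial population remaining at the end of the
        study period.  ``r = 1`` encodes the null (no trend); ``r = 0.5`` a
        halving of the population.
    cv_lower, cv_upper : float
        Bounds of the uniform distribution from which each occasion's CV of
        the abundance estimate is drawn.  Equal bounds give a fixed CV.
    baseline_abundance : float
        True abundance at the first occasion.  Cancels in the ratios; kept
        as an explicit nuisance constant.
    """

    T: int
    r: float
    cv_lower: float
    cv_upper: float
    baseline_abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.T < 3:
            raise ValueError(f"T must be >= 3, got {self.T}")
        if self.r <= 0:
            raise ValueError(f"r must be positive, got {self.r}")
        if not 0 < self.cv_lower <= self.cv_upper:
            if self.cv_lower == self.cv_upper == 0.0:
                pass  # degenerate noiseless scenario, allowed for testing
            else:
                raise ValueError(
                    "need 0 < cv_lower <= cv_upper, got "
                    f"({self.cv_lower}, {self.cv_upper})"
                )
        if self.baseline_abundance <= 0:
            raise ValueError("baseline_abundance must be positive")


@dataclass
class RatioSeries:
    """Scaled times and log abundance ratios — the regression input.

    ``x`` runs from 0 (baseline occasion) to 1 (last occasion);
    ``log_ratio[t]`` is ``log(y_t / y_1)``, so ``log_ratio[0] == 0``
    identically.
    """

    x: np.ndarray
    log_ratio: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.log_ratio = np.asarray(self.log_ratio, dtype=float)
        if self.x.shape != self.log_ratio.shape or self.x.ndim != 1:
            raise ValueError("x and log_ratio must be 1-D arrays of equal length")
        if self.x[0] != 0.0 or self.x[-1] != 1.0:
            raise ValueError("x must start at 0 and end at 1")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if self.log_ratio[0] != 0.0:
            raise ValueError("log_ratio must be 0 at the baseline occasion")

    @property
    def T(self) -> int:
        return self.x.size


@dataclass(frozen=True)
class ScenarioGridConfig:
    """Axes of the factorial scenario grid (Cartesian product)."""

    T_values: tuple = ()
    r_values: tuple = ()
    cv_settings: tuple = ()

    def __post_init__(self) -> None:
        for name in ("T_values", "r_values", "cv_settings"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, tuple(vals))

    @property
    def size(self) -> int:
        return len(self.T_values) * len(self.r_values) * len(self.cv_settings)


def default_grid_config() -> ScenarioGridConfig:
    """The full factorial design: 28 study lengths x 38 declines x 5 CV
    settings = 5,320 scenarios.

    Study lengths run from 3 to 30 occasions; the remaining fraction ``r``
    takes 38 equally spaced values from 0.50 (halving) to 0.99 (1% overall
    decline); the CV settings are a fixed CV of 0.1 plus uniform ranges with
    upper bounds 0.2 through 0.5.
    """
    return ScenarioGridConfig(
        T_values=tuple(range(3, 31)),
        r_values=tuple(np.round(np.linspace(0.50, 0.99, 38), 10)),
        cv_settings=((0.1, 0.1), (0.1, 0.2), (0.1, 0.3), (0.1, 0.4), (0.1, 0.5)),
    )


def true_proportion(r: float, t: int, T: int) -> float:
    """Fraction of the population remaining at occasion ``t``: r**((t-1)/(T-1))."""
    if r <= 0:
        raise ValueError(f"r must be positive, got {r}")
    if T < 2:
        raise ValueError(f"T must be >= 2, got {T}")
    if not 1 <= t <= T:
        raise ValueError(f"t must be in [1, {T}], got {t}")
    return float(r ** ((t - 1) / (T - 1)))


def cv_to_sdlog(cv) -> float:
    """Standard deviation on the log scale of a lognormal with the given CV.

    Uses the lognormal identity ``sigma = sqrt(log(1 + cv**2))``.
    Accepts scalars or arrays.
    """
    cv = np.asarray(cv, dtype=float)
    if np.any(cv < 0):
        raise ValueError("cv must be non-negative")
    out = np.sqrt(np.log1p(cv * cv))
    return float(out) if out.ndim == 0 else out


def simulate_series(
    scenario: Scenario,
    rng: np.random.Generator,
    *,
    baseline_noise: bool = True,
) -> RatioSeries:
    """Simulate one series of abundance estimates and return its ratios.

    Each occasion's CV is drawn ``Uniform(cv_lower, cv_upper)``; the estimate
    is ``baseline * p_t * exp(eps_t)`` with ``eps_t ~ Normal(0, sdlog(cv)^2)``
    (median-unbiased lognormal noise).  The baseline's noise ``eps_1`` enters
    the denominator of every ratio, inducing correlation across the series.

    ``baseline_noise=False`` is a diagnostic mode in which the first estimate
    is exact, making the log ratios independent — under the null the t-test
    with one fewer residual degree of freedom is then exactly calibrated.
    """
    T = scenario.T
    cvs = rng.uniform(scenario.cv_lower, scenario.cv_upper, size=T)
    sdlog = cv_to_sdlog(cvs)
    eps = rng.normal(0.0, 1.0, size=T) * sdlog
    if not baseline_noise:
        eps[0] = 0.0
    t_idx = np.arange(T, dtype=float)
    x = t_idx / (T - 1)
    log_p = x * math.log(scenario.r)
    log_y = math.log(scenario.baseline_abundance) + log_p + eps
    log_ratio = log_y - log_y[0]
    log_ratio[0] = 0.0
    return RatioSeries(x=x, log_ratio=log_ratio)


def build_scenario_grid(config: ScenarioGridConfig) -> list[Scenario]:
    """Cartesian product of the configured axes, in deterministic order
    (study length outermost, then decline, then CV setting)."""
    return [
        Scenario(T=T, r=float(r), cv_lower=float(lo), cv_upper=float(hi))
        for T, r, (lo, hi) in itertools.product(
            config.T_values, config.r_values, config.cv_settings
        )
    ]


def annual_rate_to_overall(annual_decline: float, years: int) -> float:
    """Overall decline fraction implied by a constant annual decline.

    A 1% annual decline over 30 years is an overall decline of about 26%.
    """
    if not 0 <= annual_decline < 1:
        raise ValueError("annual_decline must be in [0, 1)")
    if years < 1:
        raise ValueError("years must be >= 1")
    return 1.0 - (1.0 - annual_decline) ** years


def series_to_frame(series: RatioSeries, **ids) -> pd.DataFrame:
    """Tidy one-row-per-occasion frame of a simulated series (for export)."""
    df = pd.DataFrame(
        {
            "t": np.arange(1, series.T + 1),
            "x": series.x,
            "log_ratio": series.log_ratio,
        }
    )
    for key, value in ids.items():
        df.insert(0, key, value)
    return df
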