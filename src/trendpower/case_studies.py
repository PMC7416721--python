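"""Trend estimation for real (or synthetic) abundance-estimate series.

Takes a series of (year, abundance estimate[, CV]) for one population —
possibly unevenly spaced, between 3 and a dozen or so estimates — converts
it to the log-ratio regression input, fits a trend, and reports annual
growth rates.  The expanding-window analysis mimics an ongoing monitoring
programme by refitting on each prefix of the series, tracking how the
annual growth rate estimate stabilises as data accumulate.

Estimate-level CVs, when present in the input, are carried through for
reporting but deliberately not used as weights in the fit: the method
targets the common situation where estimates are available without a
quantitative measure of their precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import RatioSeries, cv_to_sdlog
from .trend_fit import TrendFit, fit_trend

__all__ = [
    "AbundanceSeries",
    "GrowthReport",
    "to_ratio_series",
    "annual_growth_rate",
    "expanding_window_stability",
    "generate_case_fixture",
    "read_series_csv",
    "write_series_csv",
]


@dataclass(frozen=True)
class AbundanceSeries:
    """A named series of abundance (or density) estimates by year."""

    name: str
    years: tuple
    estimates: tuple
    cv: tuple | None = None

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        estimates = tuple(float(e) for e in self.estimates)
        if len(years) != len(estimates):
            raise ValueError("years and estimates must have equal length")
        if len(years) < 3:
            raise ValueError("need at least 3 estimates for a trend fit")
        if len(set(years)) != len(years):
            raise ValueError("duplicate years in series")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValueError("years must be strictly increasing")
        if any(e <= 0 for e in estimates):
            raise ValueError("abundance estimates must be positive")
        if self.cv is not None and len(self.cv) != len(years):
            raise ValueError("cv vector must match series length")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "estimates", estimates)
        if self.cv is not None:
            object.__setattr__(self, "cv", tuple(float(c) for c in self.cv))

    def __len__(self) -> int:
        return len(self.years)

    @property
    def span_years(self) -> int:
        return self.years[-1] - self.years[0]

    def prefix(self, k: int) -> "AbundanceSeries":
        """The first k estimates, as their own series."""
        return AbundanceSeries(
            name=self.name,
            years=self.years[:k],
            estimates=self.estimates[:k],
            cv=self.cv[:k] if self.cv is not None else None,
        )


@dataclass(frozen=True)
class GrowthReport:
    """Trend fit re-expressed as an annual growth rate.

    ``r_a`` is the per-year multiplicative change implied by the fitted
    overall trend over ``span_years`` elapsed calendar years:
    ``r_a = r_hat ** (1/span_years)``.
    """

    fit: TrendFit
    r_a: float
    ci_r_a: tuple[float, float]
    span_years: int
    n_points: int | None = None


def to_ratio_series(series: AbundanceSeries) -> RatioSeries:
    """Scaled times and log ratios to the first estimate (uneven spacing ok)."""
    years = np.asarray(series.years, dtype=float)
    est = np.asarray(series.estimates, dtype=float)
    x = (years - years[0]) / (years[-1] - years[0])
    log_ratio = np.log(est) - math.log(est[0])
    log_ratio[0] = 0.0
    return RatioSeries(x=x, log_ratio=log_ratio)


def annual_growth_rate(fit: TrendFit, span_years: int, *, n_points=None) -> GrowthReport:
    """Scale an overall trend fit back to an annual timeframe."""
    if span_years < 1:
        raise ValueError("span_years must be >= 1")
    e = 1.0 / span_years
    lo, hi = fit.ci_r
    return GrowthReport(
        fit=fit,
        r_a=fit.r_hat**e,
        ci_r_a=(lo**e, hi**e),
        span_years=span_years,
        n_points=n_points,
    )


def expanding_window_stability(
    series: AbundanceSeries,
    approach: str = "cauchy",
    alpha: float = 0.20,
    **fit_kwargs,
) -> list[GrowthReport]:
    """Refit the trend on each prefix of the series (3, 4, ... N estimates).

    Each window's annual rate uses the elapsed years of that prefix.  Fit
    failures on individual windows are recorded as warnings and skipped.
    """
    reports: list[GrowthReport] = []
    for k in range(3, len(series) + 1):
        sub = series.prefix(k)
        try:
            fit = fit_trend(to_ratio_series(sub), approach, alpha, **fit_kwargs)
            reports.append(annual_growth_rate(fit, sub.span_years, n_points=k))
        except (ValueError, FloatingPointError) as err:  # pragma: no cover
            warnings.warn(f"window of {k} points failed: {err}", stacklevel=2)
    return reports


def generate_case_fixture(
    rng: np.random.Generator,
    n_points: int = 10,
    year_start: int = 2004,
    annual_rate: float = 0.95,
    cv: float = 0.2,
    *,
    baseline: float = 1000.0,
    name: str = "synthetic",
) -> AbundanceSeries:
    """Synthetic yearly series: geometric decline at ``annual_rate`` with
    lognormal observation noise of the given CV (same noise model as the
    simulator).  Stands in for real monitoring series in tests and demos."""
    if not 3 <= n_points <= 13:
        raise ValueError("n_points must lie in [3, 13]")
    if not 0 <= cv <= 0.5:
        raise ValueError("cv must lie in [0, 0.5]")
    years = tuple(range(year_start, year_start + n_points))
    sdlog = cv_to_sdlog(cv)
    eps = rng.normal(0.0, sdlog, size=n_points) if cv > 0 else np.zeros(n_points)
    estimates = baseline * annual_rate ** np.arange(n_points) * np.exp(eps)
    return AbundanceSeries(
        name=name, years=years, estimates=tuple(estimates), cv=(cv,) * n_points
    )


def read_series_csv(path) -> AbundanceSeries:
    """Read a (name?, year, estimate[, cv]) CSV with a header row.

    Rows are sorted by year with a warning if out of order; duplicate years
    are an error.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    if "year" not in cols or "estimate" not in cols:
        raise ValueError("CSV must have 'year' and 'estimate' columns")
    if not df[cols["year"]].is_monotonic_increasing:
        warnings.warn("years out of order in input; sorting", stacklevel=2)
        df = df.sort_values(cols["year"])
    name = str(df[cols["name"]].iloc[0]) if "name" in cols else "series"
    cv = tuple(df[cols["cv"]].astype(float)) if "cv" in cols else None
    return AbundanceSeries(
        name=name,
        years=tuple(df[cols["year"]].astype(int)),
        estimates=tuple(df[cols["estimate"]].astype(float)),
        cv=cv,
    )


def write_series_csv(series: AbundanceSeries, path) -> None:
    """Write a series in the same layout read_series_csv expects."""
    data = {
        "name": [series.name] * len(series),
        "year": list(series.years),
        "estimate": list(series.estimates),
    }
    if series.cv is not None:
        data["cv"] = list(series.cv)
    pd.DataFrame(data).to_csv(path, index=False)
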