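"""Monte Carlo frequency properties of the trend estimators.

For a scenario (study length, true decline, CV bounds) and an estimation
approach, this module simulates many replicate series, fits each one and
summarises the long-run behaviour of the procedure:

* **rejection rate** — the fraction of replicates with p < alpha.  This is
  the statistical power when a decline truly exists (r < 1) and the
  empirical type-I error rate under the null (r = 1).
* **type-S rate** — among significant replicates, how often the estimated
  trend has the wrong sign (e.g. an inferred increase during a true
  decline).
* **type-M ratio** — among significant replicates, the exaggeration ratio
  mean(|beta_hat|)/|log r| of the estimated to the true effect magnitude
  on the log scale (the companion ratio of mean(r_hat - 1)/(r - 1) on the
  remaining-fraction scale is emitted alongside).
* **bias** — mean(exp(beta_hat)) - r over all replicates (the bias of the
  estimated fraction remaining), with the log-scale bias as a secondary
  column.
* **coverage** — how often the 1 - alpha confidence interval contains the
  true r, both over all replicates and conditional on significance.

Conditional quantities are undefined (``None``) when no replicate is
significant, or — for the sign and magnitude errors — when the true effect
is zero (r = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .priors import informative_prior, no_prior, weakly_informative_prior
from .simulate import Scenario, simulate_series
from .trend_fit import APPROACHES, TrendFit, _fit_xy

__all__ = ["MetricSet", "compute_metrics", "run_scenario", "run_grid", "metrics_to_frame"]


@dataclass(frozen=True)
class MetricSet:
    """Monte Carlo summary for one (scenario, approach, alpha) cell."""

    scenario: Scenario
    approach: str
    alpha: float
    n_reps: int
    rejection_rate: float
    n_significant: int
    type_s_rate: float | None
    type_m_ratio: float | None
    type_m_ratio_r: float | None
    bias_r: float
    bias_beta: float
    coverage: float
    coverage_significant: float | None
    n_degenerate: int = 0


def _prior_for(approach: str, xi: float):
    if approach == "unregularized":
        return no_prior()
    if approach == "normal":
        return informative_prior()
    if approach == "cauchy":
        return weakly_informative_prior(xi)
    raise ValueError(f"approach must be one of {APPROACHES}, got {approach!r}")


def compute_metrics(fits: list[TrendFit], truth: Scenario, alpha: float) -> MetricSet:
    """Aggregate a list of replicate fits against the known truth."""
    if not fits:
        raise ValueError("need at least one fit")
    for f in fits:
        if abs(f.ci_level - (1.0 - alpha)) > 1e-12:
            raise ValueError("all fits must carry a CI at level 1 - alpha")

    n = len(fits)
    beta_true = math.log(truth.r)
    beta = np.array([f.beta_hat for f in fits])
    p = np.array([f.p_value for f in fits])
    lo = np.array([f.ci_beta[0] for f in fits])
    hi = np.array([f.ci_beta[1] for f in fits])

    sig = p < alpha
    n_sig = int(sig.sum())
    covered = (lo <= beta_true) & (beta_true <= hi)

    type_s = type_m = type_m_r = None
    if beta_true != 0.0 and n_sig > 0:
        bsig = beta[sig]
        type_s = float(np.mean(np.sign(bsig) != np.sign(beta_true)))
        type_m = float(np.mean(np.abs(bsig)) / abs(beta_true))
        type_m_r = float(np.mean(np.exp(bsig) - 1.0) / (truth.r - 1.0))

    cov_sig = float(covered[sig].mean()) if n_sig > 0 else None

    return MetricSet(
        scenario=truth,
        approach=fits[0].prior.family if fits[0].prior.family != "none" else "unregularized",
        alpha=alpha,
        n_reps=n,
        rejection_rate=n_sig / n,
        n_significant=n_sig,
        type_s_rate=type_s,
        type_m_ratio=type_m,
        type_m_ratio_r=type_m_r,
        bias_r=float(np.mean(np.exp(beta)) - truth.r),
        bias_beta=float(np.mean(beta) - beta_true),
        coverage=float(covered.mean()),
        coverage_significant=cov_sig,
        n_degenerate=sum(f.degenerate for f in fits),
    )


def run_scenario(
    scenario: Scenario,
    approach: str,
    alpha: float,
    n_reps: int,
    rng: np.random.Generator,
    *,
    xi: float = 0.025,
    em_variant: str = "with_variance",
    baseline_noise: bool = True,
    df: int | None = None,
) -> MetricSet:
    """Simulate ``n_reps`` series under the scenario, fit each with the
    chosen approach, and summarise.

    ``baseline_noise=False`` together with ``df = T - 2`` is the calibration
    diagnostic: with an exact first estimate the log ratios are independent
    and the null t-test attains its nominal level.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    prior = _prior_for(approach, xi)
    fits = []
    for _ in range(n_reps):
        series = simulate_series(scenario, rng, baseline_noise=baseline_noise)
        fits.append(
            _fit_xy(series.x, series.log_ratio, prior, alpha, em_variant=em_variant, df=df)
        )
    return compute_metrics(fits, scenario, alpha)


def _run_cell(scenario, approaches, alphas, n_reps, seed_seq, xi, em_variant):
    """All (approach, alpha) summaries for one scenario, sharing replicates."""
    rng = np.random.default_rng(seed_seq)
    series = [simulate_series(scenario, rng) for _ in range(n_reps)]
    out = []
    for approach in approaches:
        prior = _prior_for(approach, xi)
        fits = [
            _fit_xy(s.x, s.log_ratio, prior, alphas[0], em_variant=em_variant)
            for s in series
        ]
        for alpha in alphas:
            out.append(compute_metrics([f.at_level(alpha) for f in fits], scenario, alpha))
    return out


def run_grid(
    grid: list[Scenario],
    approaches=("unregularized", "normal", "cauchy"),
    alphas=(0.05, 0.20),
    n_reps: int = 10_000,
    seed: int = 0,
    *,
    xi: float = 0.025,
    em_variant: str = "with_variance",
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Factorial sweep: one row per (scenario, approach, alpha).

    Replicates are shared across approaches and significance levels within a
    scenario so that comparisons are paired.  Each scenario gets its own
    random substream spawned deterministically from the master seed, so the
    output is identical regardless of worker scheduling.
    """
    if not grid:
        raise ValueError("scenario grid is empty")
    for a in approaches:
        if a not in APPROACHES:
            raise ValueError(f"unknown approach {a!r}")
    children = np.random.SeedSequence(seed).spawn(len(grid))
    jobs = (
        delayed(_run_cell)(sc, tuple(approaches), tuple(alphas), n_reps, ss, xi, em_variant)
        for sc, ss in zip(grid, children)
    )
    cells = Parallel(n_jobs=n_jobs)(jobs)
    rows = []
    for scenario_id, cell in enumerate(cells):
        for m in cell:
            rows.append(metrics_to_row(m, scenario_id=scenario_id))
    return pd.DataFrame(rows)


def metrics_to_row(m: MetricSet, **ids) -> dict:
    """Flatten a MetricSet into a tidy row (scenario parameters inline)."""
    sc = m.scenario
    row = dict(ids)
    row.update(
        T=sc.T,
        r=sc.r,
        cv_lower=sc.cv_lower,
        cv_upper=sc.cv_upper,
        approach=m.approach,
        alpha=m.alpha,
        n_reps=m.n_reps,
        rejection_rate=m.rejection_rate,
        n_significant=m.n_significant,
        type_s_rate=m.type_s_rate,
        type_m_ratio=m.type_m_ratio,
        type_m_ratio_r=m.type_m_ratio_r,
        bias_r=m.bias_r,
        bias_beta=m.bias_beta,
        coverage=m.coverage,
        coverage_significant=m.coverage_significant,
        n_degenerate=m.n_degenerate,
    )
    return row


def metrics_to_frame(metrics: list[MetricSet]) -> pd.DataFrame:
    """Tidy frame of several MetricSet records."""
    return pd.DataFrame([metrics_to_row(m) for m in metrics])
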