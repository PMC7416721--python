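"""No-intercept log-linear trend estimation, unregularized or regularized.

The model regresses log abundance ratios ``y_t = log(yhat_t / yhat_1)`` on
scaled time ``x_t in [0, 1]`` with no intercept; the slope ``beta``
estimates ``log r``, the log of the fraction of the population remaining at
the end of the study period.  Three estimators are available:

* **unregularized** — ordinary least squares through the origin, the
  maximum-likelihood estimate ``beta = sum(x*y)/sum(x**2)``;
* **normal prior** — a ridge-type maximum a posteriori estimate under a
  Normal(0, s) prior, found by iterating the penalized normal equations
  jointly with the residual variance;
* **cauchy prior** — MAP under a heavy-tailed Cauchy(0, s) prior, fit by an
  EM scheme that represents the Cauchy as a scale mixture of normals and
  solves a ridge problem with an adaptively re-estimated prior variance at
  each step.

All three report a standard error, a two-tailed Student-t p-value and a
confidence interval on ``T - 1`` residual degrees of freedom (the anchored
baseline point, with x = 0 and y = 0, is part of the fit and of residual
counting).  The primary interface is the scikit-learn style
:class:`TrendRegressor`; the module-level ``fit_*`` functions are thin
wrappers returning a :class:`TrendFit` record.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .priors import TrendPrior, informative_prior, no_prior, weakly_informative_prior
from .simulate import RatioSeries

__all__ = [
    "TrendFit",
    "TrendRegressor",
    "fit_unregularized",
    "fit_normal_prior",
    "fit_cauchy_prior",
    "fit_trend",
    "is_significant",
]

APPROACHES = ("unregularized", "normal", "cauchy")

_DEGENERATE_TOL = 1e-12  # RSS below this (relative to sum y^2 scale) = perfect fit


@dataclass(frozen=True)
class TrendFit:
    """Result of a single trend fit.

    ``beta_hat`` estimates ``log r``; ``r_hat = exp(beta_hat)`` is the
    estimated fraction remaining.  ``ci_beta`` is the ``1 - alpha``
    equal-tailed Student-t interval and ``ci_r`` its elementwise exponential.
    ``degenerate`` flags a perfect fit (zero residual sum of squares), in
    which case the standard error is 0 and the p-value is reported as 0.
    """

    beta_hat: float
    se: float
    df: int
    p_value: float
    ci_level: float
    ci_beta: tuple[float, float]
    prior: TrendPrior
    n_iter: int = 0
    converged: bool = True
    degenerate: bool = False

    @property
    def r_hat(self) -> float:
        return math.exp(self.beta_hat)

    @property
    def ci_r(self) -> tuple[float, float]:
        return (math.exp(self.ci_beta[0]), math.exp(self.ci_beta[1]))

    def at_level(self, alpha: float) -> "TrendFit":
        """Same point estimate and p-value, CI recomputed at level 1 - alpha."""
        ci = _t_interval(self.beta_hat, self.se, self.df, alpha)
        return dataclasses.replace(self, ci_level=1.0 - alpha, ci_beta=ci)


def _t_interval(beta: float, se: float, df: int, alpha: float) -> tuple[float, float]:
    if se == 0.0:
        return (beta, beta)
    half = float(stats.t.ppf(1.0 - alpha / 2.0, df)) * se
    return (beta - half, beta + half)


def _p_value(beta: float, se: float, df: int) -> float:
    if se == 0.0:
        return 0.0
    return float(2.0 * stats.t.sf(abs(beta) / se, df))


def _core_fit(
    x: np.ndarray,
    y: np.ndarray,
    prior: TrendPrior,
    *,
    em_variant: str = "with_variance",
    max_iter: int = 100,
    tol: float = 1e-8,
    df: int | None = None,
) -> dict:
    """Shared fitting engine on precomputed sufficient statistics.

    Returns a dict of (beta, se, df, n_iter, converged, degenerate).
    """
    sxx = float(x @ x)
    sxy = float(x @ y)
    syy = float(y @ y)
    n = x.size
    if sxx <= 0.0:
        raise ValueError("design is degenerate: sum of squared times is zero")
    if df is None:
        df = n - 1
    if df < 1:
        raise ValueError("need at least one residual degree of freedom")

    def rss(b: float) -> float:
        return max(syy - 2.0 * b * sxy + b * b * sxx, 0.0)

    beta_ml = sxy / sxx
    scale_y = max(syy, 1.0)

    if prior.family == "none":
        r = rss(beta_ml)
        degenerate = r <= _DEGENERATE_TOL * scale_y
        sigma2 = r / df
        se = math.sqrt(sigma2 / sxx) if not degenerate else 0.0
        return dict(
            beta=beta_ml, se=se, df=df, n_iter=0, converged=True, degenerate=degenerate
        )

    s = float(prior.scale)
    beta = beta_ml
    sp2 = s * s  # current normal-mixture prior variance
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        sigma2 = rss(beta) / df
        if sigma2 <= _DEGENERATE_TOL * scale_y:
            # perfect fit: penalty is overwhelmed, keep current beta
            break
        if prior.family == "normal":
            sp2 = s * s
        else:  # cauchy scale mixture
            if em_variant == "map":
                sp2 = (beta * beta + s * s) / 2.0
            elif em_variant == "with_variance":
                var_beta = sigma2 / (sxx + sigma2 / sp2)
                sp2 = (beta * beta + var_beta + s * s) / 2.0
            else:
                raise ValueError(f"unknown em_variant {em_variant!r}")
        beta_new = sxy / (sxx + sigma2 / sp2)
        if n_iter > max_iter // 2:
            beta_new = 0.5 * (beta_new + beta)  # dampen possible oscillation
        if abs(beta_new - beta) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new

    r = rss(beta)
    degenerate = r <= _DEGENERATE_TOL * scale_y
    sigma2 = r / df
    if degenerate:
        se = 0.0
        converged = True
    else:
        se = math.sqrt(sigma2 / (sxx + sigma2 / sp2))
    return dict(
        beta=beta, se=se, df=df, n_iter=n_iter, converged=converged, degenerate=degenerate
    )


def _resolve_prior(prior, prior_scale, xi) -> TrendPrior:
    if isinstance(prior, TrendPrior):
        return prior
    if prior in (None, "none"):
        return no_prior()
    if prior == "normal":
        if prior_scale is not None:
            return TrendPrior(family="normal", location=0.0, scale=prior_scale)
        return informative_prior()
    if prior == "cauchy":
        if prior_scale is not None:
            return TrendPrior(family="cauchy", location=0.0, scale=prior_scale, xi=None)
        return weakly_informative_prior(xi)
    raise ValueError(f"unknown prior {prior!r}")


class TrendRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style no-intercept trend regression on log ratios.

    Parameters
    ----------
    prior : {"none", "normal", "cauchy"} or TrendPrior, default="none"
        Regularization. "normal" defaults to the informative
        halving-to-doubling prior (scale log(2)/2); "cauchy" to the
        weakly-informative prior built from ``xi``.
    prior_scale : float, optional
        Explicit prior scale overriding the family default.
    xi : float, default=0.025
        Skeptical halving probability defining the Cauchy scale.
    alpha : float, default=0.05
        Significance level; the confidence interval is at level ``1 - alpha``.
    em_variant : {"with_variance", "map"}, default="with_variance"
        Cauchy EM update of the mixture prior variance: "map" uses
        ``(beta^2 + s^2)/2`` (exact MAP fixed point), "with_variance" adds
        the current sampling variance of beta.
    max_iter, tol : EM stopping rule (|change in beta| < tol).
    df : int, optional
        Residual degrees of freedom override (default ``T - 1``).

    Attributes
    ----------
    coef_ : ndarray of shape (1,), the slope ``beta_hat`` (estimates log r).
    se_, df_, p_value_, ci_, r_hat_, ci_r_, n_iter_, converged_, degenerate_
        Inference summaries; ``fit_`` bundles them as a :class:`TrendFit`.

    Examples
    --------
    >>> import numpy as np
    >>> X = np.array([[0.0], [0.5], [1.0]])
    >>> y = np.array([0.0, -0.2, -0.5])
    >>> TrendRegressor().fit(X, y).coef_
    array([-0.48])
    """

    def __init__(
        self,
        prior="none",
        prior_scale=None,
        xi: float = 0.025,
        alpha: float = 0.05,
        em_variant: str = "with_variance",
        max_iter: int = 100,
        tol: float = 1e-8,
        df=None,
    ):
        self.prior = prior
        self.prior_scale = prior_scale
        self.xi = xi
        self.alpha = alpha
        self.em_variant = em_variant
        self.max_iter = max_iter
        self.tol = tol
        self.df = df

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_2d=False, y_numeric=True)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("TrendRegressor expects a single time feature")
            X = X[:, 0]
        if X.size < 3:
            raise ValueError("need at least 3 observations")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        prior = _resolve_prior(self.prior, self.prior_scale, self.xi)
        res = _core_fit(
            X,
            y,
            prior,
            em_variant=self.em_variant,
            max_iter=self.max_iter,
            tol=self.tol,
            df=self.df,
        )
        self.prior_ = prior
        self.coef_ = np.array([res["beta"]])
        self.se_ = res["se"]
        self.df_ = res["df"]
        self.p_value_ = _p_value(res["beta"], res["se"], res["df"])
        self.ci_ = _t_interval(res["beta"], res["se"], res["df"], self.alpha)
        self.r_hat_ = math.exp(res["beta"])
        self.ci_r_ = (math.exp(self.ci_[0]), math.exp(self.ci_[1]))
        self.n_iter_ = res["n_iter"]
        self.converged_ = res["converged"]
        self.degenerate_ = res["degenerate"]
        self.n_features_in_ = 1
        self.fit_ = TrendFit(
            beta_hat=float(self.coef_[0]),
            se=self.se_,
            df=self.df_,
            p_value=self.p_value_,
            ci_level=1.0 - self.alpha,
            ci_beta=self.ci_,
            prior=prior,
            n_iter=self.n_iter_,
            converged=self.converged_,
            degenerate=self.degenerate_,
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, ensure_2d=False)
        if X.ndim == 2:
            X = X[:, 0]
        return X * self.coef_[0]


def _series_xy(series: RatioSeries) -> tuple[np.ndarray, np.ndarray]:
    return series.x, series.log_ratio


def fit_unregularized(series: RatioSeries, alpha: float = 0.05, *, df=None) -> TrendFit:
    """Maximum-likelihood (OLS through the origin) trend fit."""
    est = TrendRegressor(prior="none", alpha=alpha, df=df)
    est.fit(*_series_xy(series))
    return est.fit_


def fit_normal_prior(
    series: RatioSeries,
    prior: TrendPrior | None = None,
    alpha: float = 0.05,
    *,
    max_iter: int = 100,
    tol: float = 1e-8,
    df=None,
) -> TrendFit:
    """MAP trend fit under a normal prior (informative default)."""
    prior = prior if prior is not None else informative_prior()
    if prior.family != "normal":
        raise ValueError("fit_normal_prior requires a normal prior")
    est = TrendRegressor(prior=prior, alpha=alpha, max_iter=max_iter, tol=tol, df=df)
    est.fit(*_series_xy(series))
    return est.fit_


def fit_cauchy_prior(
    series: RatioSeries,
    prior: TrendPrior | None = None,
    alpha: float = 0.05,
    em_variant: str = "with_variance",
    *,
    max_iter: int = 100,
    tol: float = 1e-8,
    df=None,
) -> TrendFit:
    """MAP trend fit under a Cauchy prior (weakly-informative default),
    via the scale-mixture-of-normals EM."""
    prior = prior if prior is not None else weakly_informative_prior()
    if prior.family != "cauchy":
        raise ValueError("fit_cauchy_prior requires a cauchy prior")
    est = TrendRegressor(
        prior=prior, alpha=alpha, em_variant=em_variant, max_iter=max_iter, tol=tol, df=df
    )
    est.fit(*_series_xy(series))
    return est.fit_


def fit_trend(
    series: RatioSeries,
    approach: str = "unregularized",
    alpha: float = 0.05,
    *,
    xi: float = 0.025,
    prior_scale=None,
    em_variant: str = "with_variance",
    df=None,
) -> TrendFit:
    """Dispatch on approach name: unregularized, normal, or cauchy."""
    if approach not in APPROACHES:
        raise ValueError(f"approach must be one of {APPROACHES}, got {approach!r}")
    est = TrendRegressor(
        prior="none" if approach == "unregularized" else approach,
        prior_scale=prior_scale,
        xi=xi,
        alpha=alpha,
        em_variant=em_variant,
        df=df,
    )
    est.fit(*_series_xy(series))
    return est.fit_


def is_significant(fit: TrendFit, alpha: float) -> bool:
    """Strict significance: p-value below alpha."""
    return fit.p_value < alpha


def _fit_xy(
    x: np.ndarray,
    y: np.ndarray,
    prior: TrendPrior,
    alpha: float,
    *,
    em_variant: str = "with_variance",
    df=None,
) -> TrendFit:
    """Validation-free fitting path for Monte Carlo loops.

    Identical arithmetic to :class:`TrendRegressor` (both call the same
    engine); skips array re-validation for speed.
    """
    res = _core_fit(x, y, prior, em_variant=em_variant, df=df)
    return TrendFit(
        beta_hat=res["beta"],
        se=res["se"],
        df=res["df"],
        p_value=_p_value(res["beta"], res["se"], res["df"]),
        ci_level=1.0 - alpha,
        ci_beta=_t_interval(res["beta"], res["se"], res["df"], alpha),
        prior=prior,
        n_iter=res["n_iter"],
        converged=res["converged"],
        degenerate=res["degenerate"],
    )
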