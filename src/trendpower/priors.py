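"""Priors on the log-scale trend coefficient ``beta = log r``.

Three choices are supported: no prior (maximum likelihood), an informative
normal prior, and a weakly-informative Cauchy prior.  The normal prior is
centred on 0 with scale ``log(2)/2``, covering a priori the range from a
halving to a doubling of the population over the study period (about 95% of
its mass lies within ``|beta| <= log 2``).  The Cauchy prior encodes a small
skeptical probability ``xi`` that the population halves (or doubles): its
scale is chosen so that ``P(beta > log 2) = xi``, i.e. the null of no trend
is favoured with prior odds ``(1 - xi)/xi`` (39:1 at ``xi = 0.025``).
Because the Cauchy is heavy-tailed it shrinks weak signals strongly but
yields to strong signals in the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "TrendPrior",
    "no_prior",
    "informative_prior",
    "weakly_informative_prior",
    "cauchy_scale_from_xi",
    "prior_tail_probability",
    "prior_null_odds",
]

_FAMILIES = ("none", "normal", "cauchy")


@dataclass(frozen=True)
class TrendPrior:
    """Prior on beta = log r: family, location and scale (log-r units)."""

    family: str
    location: float = 0.0
    scale: float | None = None
    xi: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}, got {self.family!r}")
        if self.family != "none":
            if self.scale is None or self.scale <= 0:
                raise ValueError("normal/cauchy priors need a positive scale")
        if self.xi is not None and not 0 < self.xi < 0.5:
            raise ValueError("xi must lie in (0, 0.5)")


def no_prior() -> TrendPrior:
    """Flat prior: estimation reduces to maximum likelihood."""
    return TrendPrior(family="none")


def informative_prior() -> TrendPrior:
    """Normal(0, log(2)/2): halving-to-doubling range over the study period."""
    return TrendPrior(family="normal", location=0.0, scale=math.log(2) / 2)


def cauchy_scale_from_xi(xi: float) -> float:
    """Cauchy scale such that ``P(beta > log 2) = xi`` for a Cauchy centred
    at 0, via ``-log(2)/tan(pi*(xi - 1/2))``."""
    if not 0 < xi < 0.5:
        raise ValueError(f"xi must lie strictly in (0, 0.5), got {xi}")
    return -math.log(2) / math.tan(math.pi * (xi - 0.5))


def weakly_informative_prior(xi: float = 0.025) -> TrendPrior:
    """Cauchy prior centred on 0 with skeptical halving probability ``xi``."""
    return TrendPrior(family="cauchy", location=0.0, scale=cauchy_scale_from_xi(xi), xi=xi)


def prior_tail_probability(prior: TrendPrior, threshold: float) -> float:
    """P(beta > threshold) under the prior density."""
    if prior.family == "normal":
        return float(stats.norm.sf(threshold, loc=prior.location, scale=prior.scale))
    if prior.family == "cauchy":
        return float(stats.cauchy.sf(threshold, loc=prior.location, scale=prior.scale))
    raise ValueError("tail probability undefined for the flat prior")


def prior_null_odds(xi: float) -> float:
    """Prior odds in favour of the no-trend null: (1 - xi)/xi."""
    if not 0 < xi < 0.5:
        raise ValueError(f"xi must lie strictly in (0, 0.5), got {xi}")
    return (1.0 - xi) / xi
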