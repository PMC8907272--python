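"""Sampling-effort assessment via incidence-based richness extrapolation.

Sampling completeness is summarised as the ratio of observed richness S_obs
to the Chao2 asymptotic (extrapolated) richness S_ex, with a
ratio-of-counts confidence interval. Chao2 estimates the number of taxa
missed from the counts of *uniques* (Q1, taxa found in exactly one level)
and *duplicates* (Q2, exactly two levels): many uniques relative to
duplicates signal many still-unseen taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import beta

from .exceptions import InsufficientDataError, UndefinedRatioError, ValidationError
from .occurrence import IncidenceMatrix


@dataclass(frozen=True)
class CoverageResult:
    """Observed vs extrapolated richness for one incidence matrix."""

    s_obs: int
    s_ex: float
    ratio: float
    ci_low: float
    ci_high: float
    q1: int
    q2: int
    t: int

    def to_dict(self) -> dict:
        return {
            "s_obs": self.s_obs,
            "s_ex": round(self.s_ex, 6),
            "ratio": round(self.ratio, 6),
            "ci_low": round(self.ci_low, 6),
            "ci_high": round(self.ci_high, 6),
            "q1": self.q1,
            "q2": self.q2,
            "t": self.t,
        }


def ratio_ci(x: int, y: int, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for the ratio x/y of two counts.

    Uses the conditional-binomial construction: given the total n = x + y,
    x ~ Binomial(n, p) with p = x/(x+y); a Clopper-Pearson interval for p
    is transformed to ratio bounds p/(1-p). Exact (conservative) for
    independent Poisson counts.
    """
    if y <= 0:
        raise UndefinedRatioError("ratio of counts undefined for y <= 0")
    if x < 0:
        raise ValidationError("counts must be non-negative")
    if not 0.0 < level < 1.0:
        raise ValidationError("confidence level must be in (0, 1)")
    n = x + y
    alpha = 1.0 - level
    p_lo = 0.0 if x == 0 else float(beta.ppf(alpha / 2.0, x, n - x + 1))
    p_hi = 1.0 if x == n else float(beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    lo = p_lo / (1.0 - p_lo)
    hi = np.inf if p_hi >= 1.0 else p_hi / (1.0 - p_hi)
    return lo, hi


def chao2_extrapolate(m: IncidenceMatrix, ci_level: float = 0.95) -> CoverageResult:
    """Chao2 asymptotic richness and the S_obs/S_ex completeness ratio.

    With t levels, Q1 uniques and Q2 duplicates::

        S_ex = S_obs + (t-1)/t * Q1^2 / (2 Q2)            if Q2 > 0
        S_ex = S_obs + (t-1)/t * Q1 (Q1 - 1) / 2          if Q2 = 0

    The CI is the ratio-of-counts interval for (S_obs, round(S_ex)); the
    extrapolated richness is rounded to the nearest integer because the
    interval is defined for counts.
    """
    t = m.n_levels
    if t < 2:
        raise InsufficientDataError(f"need at least 2 levels, got {t}")
    incidence = m.values.sum(axis=0)
    s_obs = int((incidence >= 1).sum())
    if s_obs == 0:
        raise ValidationError("all-zero incidence matrix")
    q1 = int((incidence == 1).sum())
    q2 = int((incidence == 2).sum())
    corr = (t - 1.0) / t
    if q2 > 0:
        s_ex = s_obs + corr * q1 * q1 / (2.0 * q2)
    else:
        s_ex = s_obs + corr * q1 * (q1 - 1.0) / 2.0
    ratio = s_obs / s_ex
    ci_low, ci_high = ratio_ci(s_obs, int(round(s_ex)), ci_level)
    return CoverageResult(
        s_obs=s_obs,
        s_ex=float(s_ex),
        ratio=float(ratio),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        q1=q1,
        q2=q2,
        t=t,
    )
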