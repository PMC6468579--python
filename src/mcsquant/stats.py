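"""Shared statistics: Pearson correlation with exact t-transform p-values,
Student's paired t-test, and Manders colocalization coefficients.

All p-values are two-sided and come from the t distribution; the t statistic
and degrees of freedom are reported alongside so results can be checked by
hand against the closed forms

    Pearson:  t = r * sqrt(n - 2) / sqrt(1 - r^2),      df = n - 2
    paired t: t = mean(d) / (SD(d) / sqrt(n)),           df = n - 1

with d = x - y and SD the n-1 sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "PairedTestResult",
    "MandersResult",
    "pearson_with_p",
    "pearson_p_from_r",
    "paired_t",
    "manders",
    "DegenerateTestError",
]


class DegenerateTestError(ValueError):
    """Raised when a test statistic is undefined (zero variance input)."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t_stat: float
    df: int
    p_two_sided: float


@dataclass(frozen=True)
class PairedTestResult:
    t_stat: float
    df: int
    p_two_sided: float
    mean_diff: float
    n: int


@dataclass(frozen=True)
class MandersResult:
    m1: float
    m2: float
    thr_a: float
    thr_b: float


def pearson_p_from_r(r: float, n: int) -> tuple[float, float]:
    """Map a sample Pearson r at sample size n to (t, two-sided p).

    Uses the exact t-transform t = r*sqrt(n-2)/sqrt(1-r^2) with n-2 df.
    |r| = 1 maps to p = 0.
    """
    if n < 3:
        raise ValueError("need n >= 3 for a correlation test")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation out of range: {r}")
    df = n - 2
    if abs(r) == 1.0:
        return float("inf") * np.sign(r), 0.0
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


def pearson_with_p(x, y) -> CorrelationResult:
    """Sample Pearson correlation between two equal-length profiles with its
    exact two-sided p-value from the t distribution.

    Raises :class:`DegenerateTestError` if either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateTestError("correlation undefined for constant input")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = min(1.0, max(-1.0, r))
    t, p = pearson_p_from_r(r, n)
    return CorrelationResult(r=r, n=n, t_stat=t, df=n - 2, p_two_sided=p)


def paired_t(x, y) -> PairedTestResult:
    """Two-sided Student's paired t-test on per-unit differences d = x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and aligned")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateTestError("all differences identical; t undefined")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return PairedTestResult(t_stat=t, df=n - 1, p_two_sided=p,
                            mean_diff=float(d.mean()), n=n)


def manders(ch_a, ch_b, thr_a: float = 0.0, thr_b: float = 0.0) -> MandersResult:
    """Manders colocalization coefficients of two intensity images.

    M1 is the fraction of channel-A intensity (over pixels where A > thr_a)
    that falls on pixels where B > thr_b; M2 swaps the roles. The classic
    coefficients use thresholds of 0.
    """
    a = np.asarray(ch_a, dtype=float)
    b = np.asarray(ch_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    a_sel = a > thr_a
    b_sel = b > thr_b
    denom_a = a[a_sel].sum()
    denom_b = b[b_sel].sum()
    if denom_a == 0 or denom_b == 0:
        raise DegenerateTestError("no above-threshold signal in one channel")
    m1 = float(a[a_sel & b_sel].sum() / denom_a)
    m2 = float(b[b_sel & a_sel].sum() / denom_b)
    return MandersResult(m1=m1, m2=m2, thr_a=float(thr_a), thr_b=float(thr_b))
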