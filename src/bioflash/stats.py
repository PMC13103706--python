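"""Statistical layer: geometric means with back-transformed confidence
limits, t-tests (raw data or printed summary statistics), and one-way ANOVA.

Flash parameters are approximately lognormal, so they are natural-log
transformed before inference; results are reported as the geometric mean
(the back-transformed mean of logs) with 95% confidence limits obtained by
back-transforming the t-based limits of the log-transformed values.  Group
comparisons use Student's pooled two-sample t-test by default (a Welch
variant is available), paired comparisons a one-sample t on differences, and
multi-group comparisons the classical one-way fixed-effects F.  All tests
are two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "GeometricSummary",
    "TestResult",
    "StatsError",
    "summarize",
    "geometric_mean_ci",
    "t_test_unpaired_summary",
    "t_test_unpaired_raw",
    "t_test_paired",
    "anova_oneway",
    "anova_oneway_summary",
]


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


@dataclass(frozen=True)
class GroupSummary:
    """(mean, SD, n) summary of one group, as printed in results tables."""

    mean: float
    sd: float
    n: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise StatsError("group needs n >= 2")
        if self.sd < 0:
            raise StatsError("sd must be non-negative")


@dataclass(frozen=True)
class GeometricSummary:
    """Geometric mean with back-transformed confidence limits."""

    geometric_mean: float
    ci_low: float
    ci_high: float
    n: int
    alpha: float = 0.05


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its degrees of freedom and two-sided p-value.

    ``undefined`` is set (with NaN statistic and p) when the statistic does
    not exist, e.g. zero variance everywhere.
    """

    statistic: float
    df: float
    p_value: float
    test_name: str
    two_sided: bool = True
    undefined: bool = False


def summarize(x: Sequence[float], label: str = "") -> GroupSummary:
    """Sample-based (mean, SD, n) summary with the n−1 denominator."""
    arr = np.asarray(x, dtype=float)
    if arr.size < 2:
        raise StatsError("need at least two observations")
    return GroupSummary(
        mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=int(arr.size), label=label
    )


def geometric_mean_ci(values: Sequence[float], alpha: float = 0.05) -> GeometricSummary:
    """Geometric mean and back-transformed t-based confidence limits.

    Natural-log transform; the limits are exp(mean(logs) ± t_{n−1,1−α/2} ·
    SD(logs)/√n).  The result is invariant to the logarithm base.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise StatsError("need at least two values")
    if np.any(arr <= 0):
        raise StatsError("geometric mean requires strictly positive values")
    if not 0 < alpha < 1:
        raise StatsError("alpha must be in (0, 1)")
    logs = np.log(arr)
    m = float(logs.mean())
    s = float(logs.std(ddof=1))
    n = int(arr.size)
    half = sps.t.ppf(1 - alpha / 2, n - 1) * s / math.sqrt(n)
    return GeometricSummary(
        geometric_mean=math.exp(m),
        ci_low=math.exp(m - half),
        ci_high=math.exp(m + half),
        n=n,
        alpha=alpha,
    )


def _undefined(name: str, df: float) -> TestResult:
    return TestResult(
        statistic=math.nan,
        df=df,
        p_value=math.nan,
        test_name=name,
        undefined=True,
    )


def t_test_unpaired_summary(
    g1: GroupSummary, g2: GroupSummary, pooled: bool = True
) -> TestResult:
    """Two-sample t-test from (mean, SD, n) summaries.

    Pooled (Student) variance with df = n1 + n2 − 2 by default; Welch's
    unequal-variance form with Satterthwaite df when ``pooled=False``.
    """
    n1, n2 = g1.n, g2.n
    v1, v2 = g1.sd**2, g2.sd**2
    if pooled:
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        name = "t_unpaired_pooled"
    else:
        a, b = v1 / n1, v2 / n2
        se = math.sqrt(a + b)
        df = (
            (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
            if se > 0
            else float(n1 + n2 - 2)
        )
        name = "t_unpaired_welch"
    if se == 0.0:
        return _undefined(name, df)
    t = (g1.mean - g2.mean) / se
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=t, df=df, p_value=p, test_name=name)


def t_test_unpaired_raw(
    x: Sequence[float], y: Sequence[float], pooled: bool = True
) -> TestResult:
    """Two-sample t-test on raw samples; identical to the summary form."""
    return t_test_unpaired_summary(summarize(x), summarize(y), pooled=pooled)


def t_test_paired(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Paired t-test: one-sample t on the differences, df = n − 1."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise StatsError("paired samples must have equal length")
    if xa.size < 2:
        raise StatsError("need at least two pairs")
    d = xa - ya
    n = d.size
    df = float(n - 1)
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if float(d.mean()) == 0.0:
            return TestResult(0.0, df, 1.0, "t_paired")
        return _undefined("t_paired", df)
    t = float(d.mean()) / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult(statistic=t, df=df, p_value=p, test_name="t_paired")


def anova_oneway_summary(groups: Sequence[GroupSummary]) -> TestResult:
    """One-way fixed-effects ANOVA from per-group (mean, SD, n) summaries.

    Between/within sums of squares are reconstructed from the summaries, so
    the F statistic is identical to the raw-data computation.
    """
    if len(groups) < 2:
        raise StatsError("ANOVA needs at least two groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    N = float(ns.sum())
    k = len(groups)
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    dfb, dfw = float(k - 1), float(N - k)
    if ssw == 0.0:
        return _undefined("anova_oneway", dfb)
    F = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(F, dfb, dfw))
    return TestResult(statistic=F, df=dfb, p_value=p, test_name="anova_oneway")


def anova_oneway(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA on raw groups (each with n ≥ 2)."""
    return anova_oneway_summary([summarize(g) for g in groups])
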