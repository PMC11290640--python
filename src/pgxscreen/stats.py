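"""Two-sample test kernels, correlations, and linear/robust fits.

The three two-sample tests used throughout the screening pipeline — the Welch
t-test, the Mann-Whitney-Wilcoxon rank-sum test, and the Brown–Mood median
test — are implemented here directly so that their exact small-sample
behaviour is under the package's control (the Mann-Whitney test switches to a
full exact null distribution for small untied samples, which drives the
consensus screening rule at the group sizes typical of rare driver
mutations).  Correlation coefficients and ordinary/robust linear fits are
delegated to scipy and statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb, sqrt

import numpy as np
import scipy.stats as sps
import statsmodels.api as sm

__all__ = [
    "TestResult",
    "FitResult",
    "welch_t_test",
    "mann_whitney_test",
    "mood_median_test",
    "correlation",
    "linear_fit",
    "huber_fit",
]


class DegenerateComparisonError(ValueError):
    """Raised when a two-sample comparison is statistically undefined."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str
    n1: int
    n2: int
    degenerate: bool = False


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    method: str


def _as_clean_array(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float).ravel()
    if a.size == 0 or not np.all(np.isfinite(a)):
        raise ValueError(f"{name} must be non-empty and finite")
    return a


# ---------------------------------------------------------------------------
# Welch t-test


def welch_t_test(x, y) -> TestResult:
    """Two-sample Welch t-test (unequal variances, Welch–Satterthwaite df).

    Returns the two-sided p-value.  Raises ``DegenerateComparisonError`` when
    both groups have zero variance (the statistic is undefined).
    """
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        if x.mean() == y.mean():
            # identical constants: no evidence of shift
            return TestResult(0.0, 1.0, "welch_t", n1, n2, degenerate=True)
        raise DegenerateComparisonError("degenerate comparison: both variances zero")
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(min(p, 1.0)), "welch_t", n1, n2)


# ---------------------------------------------------------------------------
# Mann-Whitney-Wilcoxon


@lru_cache(maxsize=64)
def _mwu_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution counts of the Mann-Whitney U statistic.

    ``counts[u]`` is the number of the C(n1+n2, n1) label assignments giving
    U = u, computed by the Gaussian-binomial recurrence
    N(u; m, n) = N(u; m-1, n) + N(u-m; m, n-1)
    (partitions of u into at most m parts each at most n).
    """
    umax = n1 * n2
    prev = np.zeros((n1 + 1, umax + 1))
    prev[:, 0] = 1.0  # n = 0: only u = 0
    for n in range(1, n2 + 1):
        cur = np.zeros_like(prev)
        cur[0, 0] = 1.0
        for m in range(1, n1 + 1):
            cur[m] = cur[m - 1]
            cur[m, m:] += prev[m, : umax + 1 - m]
        prev = cur
    counts = prev[n1]
    counts.setflags(write=False)
    return counts


def _mwu_exact_p(u: float, n1: int, n2: int) -> float:
    counts = _mwu_counts(n1, n2)
    total = comb(n1 + n2, n1)
    ui = int(round(u))
    cdf = counts[: ui + 1].sum() / total
    sf = counts[ui:].sum() / total
    return min(1.0, 2.0 * min(cdf, sf))


def mann_whitney_test(x, y) -> TestResult:
    """Two-sample Mann-Whitney-Wilcoxon rank-sum test, two-sided.

    Uses the exact null distribution of U when both groups have at most 50
    observations and the pooled sample is tie-free; otherwise a normal
    approximation with tie correction and continuity correction.
    """
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = np.any(tie_counts > 1)

    if not has_ties and n1 <= 50 and n2 <= 50:
        p = _mwu_exact_p(u1, n1, n2)
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = (tie_counts**3 - tie_counts).sum()
        sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term / (n * (n - 1)))
        if sigma2 <= 0:
            return TestResult(float(u1), 1.0, "mann_whitney", n1, n2, degenerate=True)
        # continuity correction toward the mean
        z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / sqrt(sigma2) if u1 != mu else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(float(u1), float(min(p, 1.0)), "mann_whitney", n1, n2)


# ---------------------------------------------------------------------------
# Brown–Mood median test


def mood_median_test(x, y, yates: bool = False) -> TestResult:
    """Brown–Mood two-sample median test.

    Pooled values are dichotomized at the common median (strictly above vs at
    or below); the resulting 2x2 table is tested with a 1-df Pearson
    chi-square (no continuity correction by default).  When every pooled
    value falls on one side of the median the comparison is degenerate and
    p = 1 is returned with the ``degenerate`` flag set.
    """
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "mood_median", n1, n2, degenerate=True)
    med = np.median(pooled)
    a = int((x > med).sum())  # x above
    b = n1 - a
    c = int((y > med).sum())  # y above
    d = n2 - c
    n = n1 + n2
    row1, row2 = a + c, b + d
    if row1 == 0 or row2 == 0:
        return TestResult(0.0, 1.0, "mood_median", n1, n2, degenerate=True)
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    chi2 = n * diff**2 / (n1 * n2 * row1 * row2)
    p = sps.chi2.sf(chi2, df=1)
    return TestResult(float(chi2), float(p), "mood_median", n1, n2)


# ---------------------------------------------------------------------------
# Correlations and fits

_CORR_FUNCS = {
    "pearson": lambda x, y: sps.pearsonr(x, y).statistic,
    "spearman": lambda x, y: sps.spearmanr(x, y).statistic,
    # tau-b: tie-adjusted, appropriate for rounded response data
    "kendall": lambda x, y: sps.kendalltau(x, y, variant="b").statistic,
}


def correlation(x, y, method: str) -> float:
    """Pearson's r, Spearman's rho, or Kendall's tau-b."""
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    try:
        f = _CORR_FUNCS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; use pearson/spearman/kendall")
    return float(f(x, y))


def _check_fit_input(x, y):
    x = _as_clean_array(x, "x")
    y = _as_clean_array(y, "y")
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.all(x == x[0]):
        raise ValueError("slope undefined for constant x")
    return x, y


def linear_fit(x, y) -> FitResult:
    """Ordinary least squares y ~ x."""
    x, y = _check_fit_input(x, y)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return FitResult(float(res.params[1]), float(res.params[0]), "lm")


def huber_fit(x, y, tol: float = 1e-8, maxiter: int = 50) -> FitResult:
    """Huber M-estimator (c = 1.345) fitted by IRLS."""
    x, y = _check_fit_input(x, y)
    model = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.HuberT(t=1.345))
    res = model.fit(maxiter=maxiter, tol=tol)
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise RuntimeError(f"robust fit did not converge; last iterate {params}")
    return FitResult(float(params[1]), float(params[0]), "rlm")
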