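"""Normality assessment and power-transform selection for drug-response pools.

Drug-response measures arrive on very different scales: viability-curve AUC
is approximately normal, EC50/IC50 concentrations are lognormal-like, and
log-fold-change (LFC) is signed.  Group comparisons downstream assume rough
normality (the Welch t-test in particular), so each (panel, measure) pool is
power-transformed first:

* nonnegative measures (AUC, EC50, IC50): a Box-Cox λ is estimated by profile
  maximum likelihood; |λ−1| ≤ 0.25 keeps the identity, |λ| ≤ 0.25 selects a
  plain log, anything else applies Box-Cox(λ);
* measures containing negative values (LFC): Yeo-Johnson at the MLE λ.

The transformed pool is then mean-centered, and the fitted spec is recorded
so later stages (and re-runs) apply exactly the same mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from math import sqrt

import numpy as np
import scipy.special
import scipy.stats as sps
from scipy.optimize import minimize_scalar

__all__ = [
    "NormalityReport",
    "TransformSpec",
    "boxcox_transform",
    "yeojohnson_transform",
    "estimate_power_lambda",
    "ks_normality",
    "select_and_apply_transform",
    "apply_transform",
    "measure_pair_correlation",
]

NONNEGATIVE_MEASURES = frozenset({"AUC", "EC50", "IC50"})
LOG_SCALE_MEASURES = frozenset({"EC50", "IC50"})  # logged before correlation
#: |λ̂ − 1| / |λ̂| proximity band for collapsing to identity / log
LAMBDA_PROXIMITY = 0.25
LAMBDA_RANGE = (-2.0, 2.0)
_GRID_STEP = 0.01
MIN_POOL_SIZE = 20


@dataclass(frozen=True)
class NormalityReport:
    """One-sample Kolmogorov-Smirnov check against a fitted normal."""

    ks_d: float
    ks_p: float
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class TransformSpec:
    measure: str
    family: str  # identity | log | boxcox | yeojohnson
    lam: float | None
    center: float

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "TransformSpec":
        return cls(**json.loads(s))


def boxcox_transform(x, lam: float) -> np.ndarray:
    """Box-Cox power transform: (x**λ − 1)/λ for λ ≠ 0, log x for λ = 0.

    Requires x > 0 (x = 0 tolerated only for λ > 0, where the transform is
    still finite).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Box-Cox requires nonnegative input")
    if np.any(x == 0) and lam <= 0:
        raise ValueError("x = 0 requires lambda > 0 in the Box-Cox family")
    return scipy.special.boxcox(x, lam)


def yeojohnson_transform(x, lam: float) -> np.ndarray:
    """Yeo-Johnson transform, defined for all real x and monotone in x."""
    x = np.asarray(x, dtype=float)
    return sps.yeojohnson(x, lmbda=lam)


def _profile_llf_grid(lams: np.ndarray, x: np.ndarray, family: str) -> np.ndarray:
    """Normal profile log-likelihood of the transformed data (Jacobian
    included), vectorized over a λ grid.  Matches scipy's boxcox_llf /
    yeojohnson_llf up to additive constants that do not depend on λ."""
    lams = np.atleast_1d(np.asarray(lams, dtype=float))
    n = x.size
    if family == "boxcox":
        logx = np.log(x[:, None])  # x > 0 guaranteed by caller
        with np.errstate(over="ignore"):
            y = np.where(
                lams == 0.0, logx, (np.exp(lams * logx) - 1.0) / np.where(lams == 0, 1, lams)
            )
        jac = (lams - 1.0) * logx.sum()
    else:  # yeojohnson
        xc = x[:, None]
        pos = xc >= 0
        log1p_abs = np.log1p(np.abs(xc))
        with np.errstate(over="ignore"):
            y_pos = np.where(
                lams == 0.0, log1p_abs,
                (np.exp(lams * log1p_abs) - 1.0) / np.where(lams == 0, 1, lams),
            )
            two_m = 2.0 - lams
            y_neg = np.where(
                two_m == 0.0, -log1p_abs,
                -(np.exp(two_m * log1p_abs) - 1.0) / np.where(two_m == 0, 1, two_m),
            )
        y = np.where(pos, y_pos, y_neg)
        jac = (lams - 1.0) * (np.sign(x) * np.log1p(np.abs(x))).sum()
    var = y.var(axis=0)  # MLE variance
    with np.errstate(divide="ignore"):
        llf = -n / 2.0 * np.log(var) + jac
    return llf


def _profile_llf(lam: float, x: np.ndarray, family: str) -> float:
    return float(_profile_llf_grid(np.array([lam]), x, family)[0])


def estimate_power_lambda(x, family: str) -> float:
    """MLE of the power parameter λ over [−2, 2].

    Maximizes the normal profile log-likelihood of the transformed data
    (Jacobian included) on a 0.01-spaced grid, then refines the best grid
    point with a bounded scalar search.  Deterministic by construction.
    """
    x = np.asarray(x, dtype=float).ravel()
    if family not in ("boxcox", "yeojohnson"):
        raise ValueError("family must be 'boxcox' or 'yeojohnson'")
    if x.size < MIN_POOL_SIZE:
        raise ValueError(f"need at least {MIN_POOL_SIZE} values to estimate lambda")
    if np.all(x == x[0]):
        raise ValueError("lambda undefined for constant input")
    lo, hi = LAMBDA_RANGE
    if family == "boxcox":
        if np.any(x < 0):
            raise ValueError("Box-Cox lambda requires nonnegative data")
        if np.any(x == 0):
            lo = _GRID_STEP  # log-likelihood diverges for lam <= 0 at x = 0
    grid = np.arange(lo, hi + _GRID_STEP / 2, _GRID_STEP)
    llf = _profile_llf_grid(grid, x, family)
    best = grid[int(np.nanargmax(llf))]
    a, b = max(lo, best - _GRID_STEP), min(hi, best + _GRID_STEP)
    res = minimize_scalar(
        lambda l: -_profile_llf(l, x, family), bounds=(a, b), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x) if res.fun <= -llf.max() else float(best)


def ks_normality(x) -> NormalityReport:
    """One-sample KS test of x against Normal(mean(x), sd(x)).

    ks_d is the sup distance between the empirical CDF and the fitted normal
    CDF; ks_p comes from the asymptotic Kolmogorov distribution evaluated at
    sqrt(n)·ks_d.  Because mean and sd are estimated from the same data the
    p-value is anti-conservative (the Lilliefors effect); it is reported as
    the screening procedure defines it.
    """
    x = np.sort(np.asarray(x, dtype=float).ravel())
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 values for the KS check")
    if x[0] == x[-1]:
        raise ValueError("KS normality undefined for constant input")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    cdf = sps.norm.cdf(x, loc=mean, scale=sd)
    i = np.arange(1, n + 1)
    d = float(max((i / n - cdf).max(), (cdf - (i - 1) / n).max()))
    p = float(scipy.special.kolmogorov(sqrt(n) * d))
    return NormalityReport(ks_d=d, ks_p=p, n=n, mean=mean, sd=sd)


def _raw_transform(family: str, lam: float | None, values: np.ndarray) -> np.ndarray:
    if family == "identity":
        return values.astype(float)
    if family == "log":
        if np.any(values <= 0):
            raise ValueError("log transform requires strictly positive values")
        return np.log(values)
    if family == "boxcox":
        return boxcox_transform(values, lam)
    if family == "yeojohnson":
        return yeojohnson_transform(values, lam)
    raise ValueError(f"unknown transform family {family!r}")


def apply_transform(spec: TransformSpec, values) -> np.ndarray:
    """Apply a previously fitted TransformSpec (transform then center)."""
    values = np.asarray(values, dtype=float)
    return _raw_transform(spec.family, spec.lam, values) - spec.center


def select_and_apply_transform(measure: str, values) -> tuple[TransformSpec, np.ndarray]:
    """Fit the transformation rule to a (panel, measure) pool and apply it.

    Returns the fitted spec and the transformed, mean-centered pool.  Pools
    below 20 values are refused: λ estimation is unstable there and raw-scale
    analysis is the better choice.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < MIN_POOL_SIZE:
        raise ValueError(
            f"pool of {values.size} < {MIN_POOL_SIZE} values: transform selection "
            "unreliable; analyze on the raw scale instead"
        )
    if np.any(~np.isfinite(values)):
        raise ValueError("pool contains non-finite values")

    if np.any(values < 0):
        lam = estimate_power_lambda(values, "yeojohnson")
        family = "yeojohnson"
    else:
        lam = estimate_power_lambda(values, "boxcox")
        if abs(lam - 1.0) <= LAMBDA_PROXIMITY:
            family, lam = "identity", None
        elif abs(lam) <= LAMBDA_PROXIMITY:
            family, lam = "log", None
        else:
            family = "boxcox"

    transformed = _raw_transform(family, lam, values)
    center = float(transformed.mean())
    spec = TransformSpec(measure=measure, family=family, lam=lam, center=center)
    return spec, transformed - center


def measure_pair_correlation(resp, drug: str, m1: str, m2: str):
    """Pearson/Spearman/Kendall correlation between two measures of one drug.

    EC50-like measures are log-transformed before correlating (their raw
    scale is heavy-tailed).  Requires at least 3 samples carrying both
    measures.
    """
    from .stats import correlation  # local import to avoid cycle at module load

    wide = resp.pivot_measures(drug, [m1, m2])
    if len(wide) < 3:
        raise ValueError(f"fewer than 3 samples have both {m1} and {m2} for {drug}")
    cols = []
    for m in (m1, m2):
        v = wide[m].to_numpy(dtype=float)
        if m in LOG_SCALE_MEASURES:
            if np.any(v <= 0):
                raise ValueError(f"{m} values must be positive for the log scale")
            v = np.log(v)
        cols.append(v)
    a, b = cols
    return (
        correlation(a, b, "pearson"),
        correlation(a, b, "spearman"),
        correlation(a, b, "kendall"),
    )
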