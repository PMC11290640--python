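"""Copy-number screening: integer binning, max-driver-CNV groups, and
per-gene CNV–response association.

Relative copy numbers sit near 1 for diploid-neutral genes; amplified genes
reach 2–6+.  Samples are grouped by the integer-binned maximum copy number
across a panel's driver genes ({1, 2, 3, 4+}; bin 0 — deletion territory —
is kept as its own label but excluded from trend summaries).  Per-gene
association uses the continuous copy number against the transformed
response: Pearson/Spearman/Kendall coefficients plus OLS and Huber fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import FitResult, correlation, huber_fit, linear_fit
from .transform import TransformSpec, apply_transform

__all__ = [
    "CnvAssociation",
    "bin_cnv",
    "max_driver_cnv_groups",
    "cnv_group_response_summary",
    "cnv_gene_association",
    "associations_to_frame",
]

TREND_BINS = ("1", "2", "3", "4+")


@dataclass(frozen=True)
class CnvAssociation:
    gene: str
    drug: str
    measure: str
    n: int
    p_cor: float = float("nan")
    s_rho: float = float("nan")
    k_tau: float = float("nan")
    lm: FitResult | None = None
    rlm: FitResult | None = None
    evaluable: bool = True
    note: str = ""


def bin_cnv(value, mode: str = "nearest"):
    """Integer-bin a nonnegative copy number.

    ``nearest`` rounds half away from zero (1.5 → 2); ``ceiling`` rounds up
    (1.2 → 2), the dichotomization used for near-neutral two-group splits.
    Accepts scalars or arrays.
    """
    v = np.asarray(value, dtype=float)
    if np.any(v < 0):
        raise ValueError("copy numbers must be nonnegative")
    if mode == "nearest":
        out = np.floor(v + 0.5)
    elif mode == "ceiling":
        out = np.ceil(v)
    else:
        raise ValueError("mode must be 'nearest' or 'ceiling'")
    out = out.astype(int)
    return int(out) if np.isscalar(value) or out.ndim == 0 else out


def _bin_label(b: int) -> str:
    return "4+" if b >= 4 else str(b)


def max_driver_cnv_groups(c, drivers, mode: str = "nearest") -> pd.DataFrame:
    """Assign each sample its max-driver-CNV bin.

    Returns a frame with columns (sample_id, max_cnv, bin), where bin is one
    of {"0", "1", "2", "3", "4+"}; every sample is assigned exactly once.
    """
    present = [g for g in sorted(set(drivers)) if g in c.df.columns]
    if not present:
        raise ValueError("no driver genes present in the copy-number matrix")
    max_cnv = c.df[present].to_numpy().max(axis=1)
    bins = bin_cnv(max_cnv, mode=mode)
    return pd.DataFrame(
        {
            "sample_id": c.sample_ids,
            "max_cnv": max_cnv,
            "bin": [_bin_label(b) for b in np.atleast_1d(bins)],
        }
    )


def cnv_group_response_summary(groups: pd.DataFrame, resp, drug: str, measure: str):
    """Per-bin descriptive summary of one (drug, measure) plus a trend check.

    Returns (summary frame, trend_tau) where trend_tau is the Kendall tau of
    numeric bin vs response over bins {1, 2, 3, 4+} (bin 0 excluded), or NaN
    when fewer than two trend bins carry data.
    """
    series = resp.values_for(drug, measure)
    joined = groups.set_index("sample_id").join(series.rename("value"), how="inner")
    joined = joined.dropna(subset=["value"])
    rows = []
    for b in ["0", *TREND_BINS]:
        vals = joined.loc[joined["bin"] == b, "value"].to_numpy()
        if vals.size == 0:
            continue
        row = {"bin": b, "n": vals.size, "mean": float(vals.mean())}
        if vals.size >= 2:
            q = np.percentile(vals, [25, 50, 75])
            row.update(q25=float(q[0]), median=float(q[1]), q75=float(q[2]))
        rows.append(row)
    summary = pd.DataFrame(rows)

    trend = joined[joined["bin"].isin(TREND_BINS)].copy()
    tau = float("nan")
    if not trend.empty:
        code = trend["bin"].map({"1": 1, "2": 2, "3": 3, "4+": 4}).to_numpy(float)
        vals = trend["value"].to_numpy(float)
        if len(np.unique(code)) >= 2 and len(np.unique(vals)) >= 2 and len(code) >= 3:
            tau = correlation(code, vals, "kendall")
    return summary, tau


def cnv_gene_association(
    c, resp, gene: str, drug: str, measure: str,
    transform: TransformSpec | None = None,
) -> CnvAssociation:
    """Correlations and linear/robust fits of continuous CNV vs response.

    The copy number is used unbinned; the response is transformed when a
    spec is supplied.  A constant CNV vector yields a not-evaluable record
    (no association is defined there).
    """
    if gene not in c.df.columns:
        raise ValueError(f"gene {gene!r} not in copy-number matrix")
    series = resp.values_for(drug, measure)
    cn = c.df[gene]
    joined = pd.concat([cn.rename("cnv"), series.rename("value")], axis=1).dropna()
    n = len(joined)
    if n < 3:
        return CnvAssociation(gene, drug, measure, n, evaluable=False,
                              note="fewer than 3 paired samples")
    x = joined["cnv"].to_numpy(float)
    y = joined["value"].to_numpy(float)
    if transform is not None:
        y = apply_transform(transform, y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CnvAssociation(gene, drug, measure, n, evaluable=False,
                              note="constant CNV or response")
    return CnvAssociation(
        gene=gene, drug=drug, measure=measure, n=n,
        p_cor=correlation(x, y, "pearson"),
        s_rho=correlation(x, y, "spearman"),
        k_tau=correlation(x, y, "kendall"),
        lm=linear_fit(x, y),
        rlm=huber_fit(x, y),
    )


def associations_to_frame(assocs) -> pd.DataFrame:
    rows = [
        {
            "gene": a.gene,
            "drug": a.drug,
            "measure": a.measure,
            "n": a.n,
            "P.cor": a.p_cor,
            "S.rho": a.s_rho,
            "K.tau": a.k_tau,
            "lm.slope": a.lm.slope if a.lm else float("nan"),
            "rlm.slope": a.rlm.slope if a.rlm else float("nan"),
            "evaluable": a.evaluable,
        }
        for a in assocs
    ]
    return pd.DataFrame(rows)
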