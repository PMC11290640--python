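"""Gene × drug sensitivity maps: signed reciprocal-significance scores and
hierarchically ordered matrices.

A map cell holds the reciprocal of the Welch t p-value, signed by the
direction of the effect: positive when the mutation is sensitizing (lower
EC50/IC50, higher AUC, lower LFC in the mutated group), negative when it
confers resistance.  For CNV-based maps the cell is instead the Pearson
correlation of continuous copy number with response.  Rows (genes) and
columns (drugs) are ordered by agglomerative clustering with complete
linkage on Euclidean distance; missing cells are imputed as 0 for the
clustering only and exported as NA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .snv import GroupComparison

__all__ = ["SensitivityMap", "signed_significance", "build_map", "export_map"]

#: p-values are floored here before taking reciprocals so scores stay finite
P_FLOOR = 1e-300

#: direction in which *smaller* transformed response means *more sensitive*;
#: AUC is the opposite (higher AUC = more kill across the dose range).  The
#: LFC entry is a package convention (stronger kill = lower fold-change) and
#: can be overridden via ``lower_is_sensitive``.
LOWER_IS_SENSITIVE_DEFAULT = {"EC50": True, "IC50": True, "AUC": False, "LFC": True}


@dataclass
class SensitivityMap:
    genes: list[str]
    drugs: list[str]
    scores: np.ndarray  # gene × drug, 0-imputed where missing
    missing: np.ndarray  # boolean mask of imputed cells
    row_order: list[int]
    col_order: list[int]
    source: str  # snv_p | cnv_r
    measure: str

    def ordered_frame(self) -> pd.DataFrame:
        """Scores in clustered order, missing cells as NaN."""
        vals = self.scores.astype(float).copy()
        vals[self.missing] = np.nan
        df = pd.DataFrame(vals, index=self.genes, columns=self.drugs)
        return df.iloc[self.row_order, self.col_order]


def signed_significance(
    comp: GroupComparison, lower_is_sensitive: dict | None = None
) -> float:
    """Signed reciprocal-p score for one gene × drug comparison.

    sign = +1 when the mutated group's mean indicates sensitization under
    the measure's direction convention, −1 for resistance, 0 on an exact
    mean tie; the magnitude is 1/p_t (p floored at 1e-300).
    """
    if not comp.evaluable:
        raise ValueError("not-evaluable comparison has no score (render as missing)")
    if not np.isfinite(comp.p_t) or comp.p_t <= 0:
        raise ValueError("score requires a positive Welch t p-value")
    conventions = dict(LOWER_IS_SENSITIVE_DEFAULT)
    if lower_is_sensitive:
        conventions.update(lower_is_sensitive)
    try:
        lower = conventions[comp.measure]
    except KeyError:
        raise ValueError(f"no direction convention for measure {comp.measure!r}")
    if comp.mean_mut == comp.mean_unmut:
        return 0.0
    sensitizing = (comp.mean_mut < comp.mean_unmut) == lower
    sign = 1.0 if sensitizing else -1.0
    return sign / max(comp.p_t, P_FLOOR)


def _cluster_order(mat: np.ndarray) -> list[int]:
    if mat.shape[0] < 2:
        return list(range(mat.shape[0]))
    z = linkage(pdist(mat, metric="euclidean"), method="complete")
    return [int(i) for i in leaves_list(z)]


def build_map(cells: dict, source: str, measure: str) -> SensitivityMap:
    """Assemble a clustered map from {(gene, drug): value} cells.

    ``source`` is ``snv_p`` for signed-significance scores or ``cnv_r`` for
    CNV Pearson correlations.  Requires at least 2 genes and 2 drugs with
    values; smaller collections are better served by a flat table.  Label
    order (hence clustering tie-breaks) follows first appearance in
    ``cells``.
    """
    if source not in ("snv_p", "cnv_r"):
        raise ValueError("source must be 'snv_p' or 'cnv_r'")
    genes = list(dict.fromkeys(g for g, _ in cells))
    drugs = list(dict.fromkeys(d for _, d in cells))
    if len(genes) < 2 or len(drugs) < 2:
        raise ValueError(
            "need at least 2 genes and 2 drugs to build a map; "
            "emit a flat table for smaller collections"
        )
    scores = np.zeros((len(genes), len(drugs)))
    missing = np.ones_like(scores, dtype=bool)
    gi = {g: i for i, g in enumerate(genes)}
    di = {d: j for j, d in enumerate(drugs)}
    for (g, d), v in cells.items():
        if v is None or not np.isfinite(v):
            continue
        scores[gi[g], di[d]] = float(v)
        missing[gi[g], di[d]] = False
    return SensitivityMap(
        genes=genes,
        drugs=drugs,
        scores=scores,
        missing=missing,
        row_order=_cluster_order(scores),
        col_order=_cluster_order(scores.T),
        source=source,
        measure=measure,
    )


def export_map(smap: SensitivityMap, prefix, image: bool = False) -> list[str]:
    """Write the map as TSV (clustered order, NA for missing) + JSON metadata,
    optionally with a PNG heatmap.  Returns the written paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv = prefix.with_suffix(".tsv")
    smap.ordered_frame().to_csv(tsv, sep="\t", na_rep="NA", index_label="gene")
    meta = {
        "source": smap.source,
        "measure": smap.measure,
        "genes": smap.genes,
        "drugs": smap.drugs,
        "row_order": smap.row_order,
        "col_order": smap.col_order,
        "n_missing": int(smap.missing.sum()),
    }
    js = prefix.with_suffix(".json")
    js.write_text(json.dumps(meta, indent=1))
    written = [str(tsv), str(js)]
    if image:
        written.append(_render_heatmap(smap, prefix.with_suffix(".png")))
    return written


def _render_heatmap(smap: SensitivityMap, path) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = smap.ordered_frame()
    vals = df.to_numpy()
    # reciprocal scores are heavy-tailed: clip for color mapping only
    clip = 1.0 / 0.001 if smap.source == "snv_p" else 1.0
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(smap.drugs)),
                                    max(3, 0.3 * len(smap.genes))))
    im = ax.imshow(np.clip(vals, -clip, clip), cmap="RdBu_r",
                   vmin=-clip, vmax=clip, aspect="auto")
    ax.set_xticks(range(len(df.columns)), df.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(df.index)), df.index, fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)
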