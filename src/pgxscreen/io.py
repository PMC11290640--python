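"""Cohort input/output: mutation and copy-number matrices, response tables,
and cancer panel configuration.

The data model is deliberately small: a binary sample × gene SNV matrix, a
nonnegative sample × gene relative copy-number matrix (neutral ≈ 1), a
long-format response table keyed by (sample, drug, measure), and per-cancer
panels naming the drugs, Cancer Gene Census driver genes, and measures to
screen.  Sample identifiers are opaque strings; joins across inputs are by
exact match, and unmatched samples are dropped with a count.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MEASURES",
    "MutationMatrix",
    "CopyNumberMatrix",
    "ResponseTable",
    "CancerPanel",
    "LoadReport",
    "read_mutation_matrix",
    "read_copy_number_matrix",
    "read_response_table",
    "load_panel_config",
    "write_matrix",
    "write_response_table",
    "strip_depmap_header",
    "align_samples",
]

logger = logging.getLogger(__name__)

MEASURES = ("AUC", "EC50", "LFC", "IC50")

_DEPMAP_HEADER = re.compile(r"^\s*(\S+)\s*\(\s*\d+\s*\)\s*$")


class ValidationError(ValueError):
    """Input data violating the cohort data model."""


@dataclass
class LoadReport:
    path: str = ""
    n_rows: int = 0
    drop_count: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def strip_depmap_header(name: str) -> str:
    """Strip a DepMap-style ``SYMBOL (entrez-id)`` header to ``SYMBOL``.

    Idempotent: plain symbols are returned unchanged.
    """
    m = _DEPMAP_HEADER.match(name)
    return m.group(1) if m else name.strip()


def _check_ids(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")
    return ids


class _GeneMatrix:
    """Common behaviour of the two sample × gene matrices."""

    def __init__(self, df: pd.DataFrame):
        _check_ids(df.index, "sample ids")
        _check_ids(df.columns, "gene ids")
        self.df = df
        self._validate()

    def _validate(self):  # pragma: no cover - overridden
        raise NotImplementedError

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def shape(self):
        return self.df.shape

    def subset_samples(self, samples):
        return type(self)(self.df.loc[list(samples)])


class MutationMatrix(_GeneMatrix):
    """Binary sample × gene SNV calls (1 = the gene carries ≥1 SNV)."""

    def _validate(self):
        vals = self.df.to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary SNV call {vals[r, c]!r} at sample "
                f"{self.df.index[r]!r}, gene {self.df.columns[c]!r}"
            )
        self.df = self.df.astype(np.int8)

    @property
    def calls(self) -> np.ndarray:
        return self.df.to_numpy()


class CopyNumberMatrix(_GeneMatrix):
    """Nonnegative relative copy numbers, neutral ≈ 1."""

    def _validate(self):
        vals = self.df.to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid copy number {vals[r, c]!r} at sample "
                f"{self.df.index[r]!r}, gene {self.df.columns[c]!r}"
            )
        self.df = self.df.astype(float)

    @property
    def cn(self) -> np.ndarray:
        return self.df.to_numpy()


class ResponseTable:
    """Long-format drug-response records (sample, drug, measure, value)."""

    COLUMNS = ("sample_id", "drug", "measure", "value")

    def __init__(self, df: pd.DataFrame, report: LoadReport | None = None):
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["drug"] = df["drug"].astype(str)
        df["measure"] = df["measure"].astype(str)
        df["value"] = df["value"].astype(float)
        unknown = set(df["measure"]) - set(MEASURES)
        if unknown:
            raise ValidationError(
                f"unknown measure label(s) {sorted(unknown)}; accepted: {list(MEASURES)}"
            )
        dup = df.duplicated(subset=["sample_id", "drug", "measure"])
        if dup.any():
            key = df.loc[dup.idxmax(), ["sample_id", "drug", "measure"]].tolist()
            raise ValidationError(f"duplicate (sample, drug, measure) record: {key}")
        nonneg = df["measure"].isin(("AUC", "EC50")) & (df["value"] < 0)
        if nonneg.any():
            row = df[nonneg].iloc[0]
            raise ValidationError(
                f"negative {row['measure']} value {row['value']} for sample "
                f"{row['sample_id']!r}, drug {row['drug']!r}"
            )
        self.df = df.reset_index(drop=True)
        self.report = report or LoadReport(n_rows=len(df))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    def values_for(self, drug: str, measure: str) -> pd.Series:
        """Series of values indexed by sample id for one (drug, measure)."""
        sub = self.df[(self.df["drug"] == drug) & (self.df["measure"] == measure)]
        return sub.set_index("sample_id")["value"]

    def pool(self, drugs, measure: str) -> np.ndarray:
        """All values of one measure across a set of drugs (panel pool)."""
        sub = self.df[self.df["drug"].isin(list(drugs)) & (self.df["measure"] == measure)]
        return sub["value"].to_numpy()

    def pivot_measures(self, drug: str, measures) -> pd.DataFrame:
        """Samples × measures wide frame for one drug; rows complete in all."""
        sub = self.df[self.df["drug"] == drug]
        wide = sub.pivot(index="sample_id", columns="measure", values="value")
        missing = [m for m in measures if m not in wide.columns]
        if missing:
            raise ValidationError(f"drug {drug!r} has no {missing} records")
        return wide[list(measures)].dropna()

    def subset_samples(self, samples) -> "ResponseTable":
        keep = self.df["sample_id"].isin(set(samples))
        return ResponseTable(self.df[keep])


@dataclass(frozen=True)
class CancerPanel:
    """A cancer type's screening configuration: drugs, drivers, measures."""

    cancer_code: str
    drugs: tuple[str, ...]
    driver_genes: tuple[str, ...]
    measures: tuple[str, ...]

    def __post_init__(self):
        if not self.drugs:
            raise ValidationError(f"panel {self.cancer_code}: empty drug list")
        if not self.driver_genes:
            raise ValidationError(f"panel {self.cancer_code}: empty driver gene list")
        for coll, what in ((self.drugs, "drugs"), (self.driver_genes, "driver genes")):
            if len(set(coll)) != len(coll):
                raise ValidationError(f"panel {self.cancer_code}: duplicate {what}")
        bad = set(self.measures) - set(MEASURES)
        if bad or not self.measures:
            raise ValidationError(
                f"panel {self.cancer_code}: measures must be a non-empty subset of "
                f"{list(MEASURES)} (got {list(self.measures)})"
            )


# ---------------------------------------------------------------------------
# Readers / writers


def _read_table(path) -> pd.DataFrame:
    # delimiter sniffed between comma and tab
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def _read_gene_matrix(path, dialect: str):
    df = _read_table(path)
    if dialect not in ("plain", "depmap-header", "auto"):
        raise ValueError("dialect must be 'plain', 'depmap-header', or 'auto'")
    if dialect == "auto":
        dialect = (
            "depmap-header"
            if len(df.columns) and all(_DEPMAP_HEADER.match(str(c)) for c in df.columns)
            else "plain"
        )
    if dialect == "depmap-header":
        stripped = [strip_depmap_header(str(c)) for c in df.columns]
        if len(set(stripped)) != len(stripped):
            dupes = sorted({s for s in stripped if stripped.count(s) > 1})
            raise ValidationError(f"duplicate gene symbols after header stripping: {dupes}")
        df.columns = stripped
    else:
        df.columns = [str(c).strip() for c in df.columns]
    df.index = [str(i) for i in df.index]
    return df


def read_mutation_matrix(path, dialect: str = "auto") -> MutationMatrix:
    """Read a binary SNV matrix (first column = sample id, columns = genes)."""
    return MutationMatrix(_read_gene_matrix(path, dialect))


def read_copy_number_matrix(path, dialect: str = "auto") -> CopyNumberMatrix:
    """Read a relative copy-number matrix (same layout as the SNV matrix)."""
    return CopyNumberMatrix(_read_gene_matrix(path, dialect))


def read_response_table(path) -> ResponseTable:
    """Read a long-format response table; NA-valued rows are dropped and
    counted in the attached load report."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    rename = {"sample": "sample_id", "sample_id": "sample_id"}
    df = df.rename(columns=rename)
    required = set(ResponseTable.COLUMNS)
    if not required <= set(df.columns):
        raise ValidationError(
            f"response table must have columns {sorted(required)} "
            f"(case-insensitive); found {list(df.columns)}"
        )
    n0 = len(df)
    df = df.dropna(subset=["value"])
    report = LoadReport(path=str(path), n_rows=len(df), drop_count=n0 - len(df))
    if report.drop_count:
        logger.info("dropped %d NA-valued rows from %s", report.drop_count, path)
    return ResponseTable(df, report=report)


def load_panel_config(path) -> list[CancerPanel]:
    """Load panel configuration (YAML, one section per cancer, in file order).

    Expected layout::

        panels:
          - cancer: SKCM
            drugs: [dabrafenib, vemurafenib, ...]
            driver_genes: [BRAF, NRAS, ...]
            measures: [AUC, EC50, LFC]
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    sections = cfg["panels"] if isinstance(cfg, dict) and "panels" in cfg else cfg
    panels = []
    for sec in sections:
        panels.append(
            CancerPanel(
                cancer_code=str(sec["cancer"]),
                drugs=tuple(str(d) for d in sec["drugs"] or ()),
                driver_genes=tuple(str(g).upper() for g in sec["driver_genes"] or ()),
                measures=tuple(str(m).upper() for m in sec["measures"] or ()),
            )
        )
    return panels


def write_matrix(matrix, path, sep: str = ",") -> None:
    """Write a mutation or copy-number matrix; round-trips with the readers."""
    matrix.df.to_csv(path, sep=sep, index_label="sample_id")


def write_response_table(resp: ResponseTable, path, sep: str = ",") -> None:
    resp.df.to_csv(path, sep=sep, index=False)


def align_samples(resp: ResponseTable, *matrices):
    """Intersect samples across the response table and any gene matrices.

    Returns (resp, matrices..., n_dropped) restricted to the common samples,
    preserving each object's own sample order.
    """
    common = set(resp.df["sample_id"])
    for m in matrices:
        common &= set(m.sample_ids)
    if not common:
        raise ValidationError("no overlapping samples between inputs")
    all_ids = set(resp.df["sample_id"]).union(*(m.sample_ids for m in matrices))
    n_dropped = len(all_ids) - len(common)
    if n_dropped:
        logger.info("dropped %d samples absent from some input", n_dropped)
    out = [resp.subset_samples(common)]
    for m in matrices:
        keep = [s for s in m.sample_ids if s in common]
        out.append(m.subset_samples(keep))
    out.append(n_dropped)
    return tuple(out)
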