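"""Driver-SNV screening: mutation-defined groups, three-test comparisons,
and consensus biomarker calling.

For each (gene, drug, measure) the samples are split into mutated and
unmutated groups and compared with the Welch t-test, the Mann-Whitney test,
and the Brown–Mood median test.  A gene is called a biomarker for a drug
under the strict consensus rule when all three p-values are below 0.05 or
any one is below 0.01; the relaxed rule (used for validation-style screens)
requires at least two of the three below 0.05.  Called genes are categorized
by how many of the panel's drugs they affect ({1, 2, 3+}), and genes can be
ranked by how many cancers they are called in.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import (
    DegenerateComparisonError,
    mann_whitney_test,
    mood_median_test,
    welch_t_test,
)
from .transform import TransformSpec, apply_transform

__all__ = [
    "DRIVER_SET",
    "GroupComparison",
    "ScreeningRule",
    "BiomarkerCall",
    "partition_by_driver_set",
    "partition_by_gene",
    "compare_groups",
    "screen_panel_genes",
    "passes_rule",
    "call_biomarkers",
    "categorize_by_drug_count",
    "cross_cancer_span",
    "comparisons_to_frame",
]

logger = logging.getLogger(__name__)

#: target label for the pooled driver-set comparison (reported separately
#: from per-gene screening)
DRIVER_SET = "DRIVER_SET"

MIN_GROUP_SIZE = 2


@dataclass(frozen=True)
class GroupComparison:
    """One mutated-vs-unmutated comparison for a (target, drug, measure)."""

    target: str
    drug: str
    measure: str
    n_mut: int
    n_unmut: int
    mean_mut: float = float("nan")
    mean_unmut: float = float("nan")
    p_t: float = float("nan")
    p_w: float = float("nan")
    p_m: float = float("nan")
    evaluable: bool = True
    note: str = ""

    @property
    def p_values(self) -> tuple[float, float, float]:
        return (self.p_t, self.p_w, self.p_m)


@dataclass(frozen=True)
class ScreeningRule:
    """Consensus p-value screening rule.

    ``strict``: all three p < 0.05, or any p < 0.01.
    ``relaxed``: at least two of the three p < 0.05.
    The 0.1 rung of the threshold ladder is annotation-only ("weak evidence")
    and never triggers a call.
    """

    mode: str = "strict"
    thresholds: tuple[float, float, float] = (0.01, 0.05, 0.1)

    def __post_init__(self):
        if self.mode not in ("strict", "relaxed"):
            raise ValueError("mode must be 'strict' or 'relaxed'")
        t = self.thresholds
        if not (t[0] < t[1] < t[2]):
            raise ValueError("thresholds must be strictly increasing")


@dataclass
class BiomarkerCall:
    gene: str
    measure: str
    affected_drugs: list[str]
    category: str
    evidence: list[GroupComparison] = field(default_factory=list)


def partition_by_driver_set(m, drivers) -> tuple[list[str], list[str]]:
    """Split samples into (any driver mutated, none mutated).

    Driver genes absent from the matrix are dropped with a warning; an empty
    intersection is an error.
    """
    present = [g for g in drivers if g in m.df.columns]
    missing = [g for g in drivers if g not in m.df.columns]
    if missing:
        warnings.warn(f"{len(missing)} driver genes absent from matrix: {missing[:5]}")
    if not present:
        raise ValueError("no driver genes present in the mutation matrix")
    any_mut = m.df[present].to_numpy().any(axis=1)
    samples = np.asarray(m.sample_ids)
    return list(samples[any_mut]), list(samples[~any_mut])


def partition_by_gene(m, gene: str) -> tuple[list[str], list[str]]:
    """Split samples by the SNV status of a single gene."""
    if gene not in m.df.columns:
        raise ValueError(f"gene {gene!r} not in mutation matrix")
    mut = m.df[gene].to_numpy().astype(bool)
    samples = np.asarray(m.sample_ids)
    return list(samples[mut]), list(samples[~mut])


def compare_groups(
    resp,
    partition: tuple[list[str], list[str]],
    drug: str,
    measure: str,
    transform: TransformSpec | None = None,
    target: str = DRIVER_SET,
) -> GroupComparison:
    """Run the three two-sample tests on a mutation partition.

    Values are transformed (and centered) with ``transform`` when given.
    Groups with fewer than 2 response values make the comparison
    not-evaluable rather than raising: such records are counted in run
    reports and excluded from screening.
    """
    mutated, unmutated = partition
    series = resp.values_for(drug, measure)
    x = series.reindex(mutated).dropna().to_numpy()
    y = series.reindex(unmutated).dropna().to_numpy()
    if transform is not None:
        if transform.measure != measure:
            raise ValueError(
                f"transform fitted for {transform.measure}, applied to {measure}"
            )
        x = apply_transform(transform, x)
        y = apply_transform(transform, y)
    n1, n2 = len(x), len(y)
    if n1 < MIN_GROUP_SIZE or n2 < MIN_GROUP_SIZE:
        return GroupComparison(
            target, drug, measure, n1, n2, evaluable=False,
            note=f"group below minimum size {MIN_GROUP_SIZE}",
        )
    try:
        t_res = welch_t_test(x, y)
    except DegenerateComparisonError:
        return GroupComparison(
            target, drug, measure, n1, n2,
            mean_mut=float(np.mean(x)), mean_unmut=float(np.mean(y)),
            evaluable=False, note="degenerate: both groups constant",
        )
    w_res = mann_whitney_test(x, y)
    m_res = mood_median_test(x, y)
    return GroupComparison(
        target=target, drug=drug, measure=measure, n_mut=n1, n_unmut=n2,
        mean_mut=float(np.mean(x)), mean_unmut=float(np.mean(y)),
        p_t=t_res.p, p_w=w_res.p, p_m=m_res.p,
    )


def screen_panel_genes(
    mut, resp, panel, measure: str, transform: TransformSpec | None = None
) -> list[GroupComparison]:
    """Per-gene comparisons for every (driver gene, drug) of a panel.

    Driver genes missing from the matrix are skipped (with a log entry);
    the pooled DRIVER_SET comparison is not included here — it is reported
    separately by the pipeline.
    """
    out = []
    for gene in panel.driver_genes:
        if gene not in mut.df.columns:
            logger.info("panel %s: gene %s absent from SNV matrix", panel.cancer_code, gene)
            continue
        part = partition_by_gene(mut, gene)
        for drug in panel.drugs:
            out.append(
                compare_groups(resp, part, drug, measure, transform, target=gene)
            )
    return out


def passes_rule(p_t: float, p_w: float, p_m: float, rule: ScreeningRule) -> bool:
    """Apply the consensus screening rule to one p-value triple.

    All inequalities are strict; NaN p-values never pass.
    """
    ps = (p_t, p_w, p_m)
    if any(not np.isfinite(p) for p in ps):
        return False
    strong, moderate, _ = rule.thresholds
    if rule.mode == "strict":
        return all(p < moderate for p in ps) or min(ps) < strong
    return sum(p < moderate for p in ps) >= 2


def categorize_by_drug_count(n_drugs: int) -> str:
    """Drug-count category for a called gene: {1, 2, 3+}."""
    if n_drugs < 1:
        raise ValueError("a biomarker call needs at least one affected drug")
    return str(n_drugs) if n_drugs < 3 else "3+"


def call_biomarkers(
    comparisons, rule: ScreeningRule, bh_adjust: bool = False
) -> list[BiomarkerCall]:
    """Aggregate passing (gene, drug) comparisons into per-gene calls.

    Comparisons must share a measure; driver-set comparisons and
    not-evaluable records are ignored.  Calls are returned in first-seen
    gene order, each with its drug list, {1,2,3+} category, and evidence.

    ``bh_adjust`` applies a Benjamini–Hochberg correction to each test's
    p-value family before screening.  It is off by default — the consensus
    rule operates on raw p-values — and turning it on is a deliberate
    deviation toward family-wise control.
    """
    comps = [c for c in comparisons if c.evaluable and c.target != DRIVER_SET]
    measures = {c.measure for c in comps}
    if len(measures) > 1:
        raise ValueError(f"comparisons mix measures {sorted(measures)}")
    if bh_adjust and comps:
        from statsmodels.stats.multitest import multipletests

        adjusted = {
            attr: multipletests([getattr(c, attr) for c in comps], method="fdr_bh")[1]
            for attr in ("p_t", "p_w", "p_m")
        }
        triples = list(zip(adjusted["p_t"], adjusted["p_w"], adjusted["p_m"]))
    else:
        triples = [c.p_values for c in comps]
    by_gene: dict[str, list[GroupComparison]] = {}
    for c, (pt, pw, pm) in zip(comps, triples):
        if passes_rule(pt, pw, pm, rule):
            by_gene.setdefault(c.target, []).append(c)
    calls = []
    for gene, evid in by_gene.items():
        drugs = [c.drug for c in evid]
        calls.append(
            BiomarkerCall(
                gene=gene,
                measure=evid[0].measure,
                affected_drugs=drugs,
                category=categorize_by_drug_count(len(drugs)),
                evidence=evid,
            )
        )
    return calls


def cross_cancer_span(calls_by_panel: dict) -> dict[str, int]:
    """Number of distinct cancers in which each gene has ≥1 biomarker call.

    Sorted by descending span, then alphabetically.
    """
    spans: dict[str, set] = {}
    for panel_code, calls in calls_by_panel.items():
        for call in calls:
            spans.setdefault(call.gene, set()).add(panel_code)
    items = sorted(spans.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return {gene: len(panels) for gene, panels in items}


def evidence_tier(p_t: float, p_w: float, p_m: float,
                  thresholds=(0.01, 0.05, 0.1)) -> str:
    """Annotation tier from the threshold ladder: strong (< 0.01), moderate
    (< 0.05), weak (< 0.1) by the smallest p-value; the weak tier never
    triggers a biomarker call."""
    ps = [p for p in (p_t, p_w, p_m) if np.isfinite(p)]
    if not ps:
        return "none"
    strong, moderate, weak = thresholds
    m = min(ps)
    if m < strong:
        return "strong"
    if m < moderate:
        return "moderate"
    if m < weak:
        return "weak"
    return "none"


def comparisons_to_frame(comparisons) -> pd.DataFrame:
    """Tabulate comparisons in the worked-example column layout."""
    rows = [
        {
            "Gene": c.target,
            "Drug": c.drug,
            "Measure": c.measure,
            "p.t": c.p_t,
            "p.w": c.p_w,
            "p.m": c.p_m,
            "No. mutated": c.n_mut,
            "No. unmutated": c.n_unmut,
            "mean.mut": c.mean_mut,
            "mean.unmut": c.mean_unmut,
            "evidence": evidence_tier(c.p_t, c.p_w, c.p_m) if c.evaluable
            else "none",
            "evaluable": c.evaluable,
        }
        for c in comparisons
    ]
    return pd.DataFrame(rows)
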