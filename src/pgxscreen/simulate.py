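"""Synthetic pharmacogenomic cohorts with planted gene–drug effects.

The generator emulates the statistical structure of pooled cell-line drug
screens: per-sample AUC near-normal around 1, EC50 lognormal, LFC centered
at 0, relative copy numbers normal around 1 with rare amplifications, and
binary driver SNVs at gene-specific frequencies.  Planted SNV effects are
additive on the analysis (transformed) scale in pooled-SD units, so a
sensitizing effect of δ = 1 moves the mutated group's mean by one standard
deviation in the sensitive direction of the measure; EC50 effects act on
the log scale.  CNV effects are linear slopes per copy above neutral.
Ground truth is carried alongside the cohort for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CopyNumberMatrix, MutationMatrix, ResponseTable, CancerPanel
from .io import write_matrix, write_response_table

__all__ = [
    "CohortSpec",
    "SnvEffect",
    "CnvEffect",
    "SyntheticTruth",
    "generate_cohort",
    "make_null_spec",
    "panel_for_spec",
    "write_cohort",
]

#: direction sign per measure: the shift applied for a *sensitizing* effect
_SENSITIZING_SIGN = {"AUC": +1.0, "EC50": -1.0, "IC50": -1.0, "LFC": -1.0}


@dataclass(frozen=True)
class SnvEffect:
    gene: str
    drug: str
    measure: str
    delta: float  # pooled-SD units on the analysis scale
    direction: str = "sensitizing"  # or "resistant"

    def __post_init__(self):
        if self.direction not in ("sensitizing", "resistant"):
            raise ValueError("direction must be 'sensitizing' or 'resistant'")


@dataclass(frozen=True)
class CnvEffect:
    gene: str
    drug: str
    measure: str
    beta: float  # slope per copy above neutral, analysis scale


@dataclass(frozen=True)
class SyntheticTruth:
    snv_effects: tuple[SnvEffect, ...] = ()
    cnv_effects: tuple[CnvEffect, ...] = ()

    @classmethod
    def empty(cls) -> "SyntheticTruth":
        return cls()


@dataclass(frozen=True)
class CohortSpec:
    """Cohort dimensions and base response/genomics models.

    Defaults mirror the screens the pipeline targets: AUC ~ Normal(1, 0.15)
    truncated at 0, EC50 ~ exp(Normal(0, 1)), LFC ~ Normal(0, 1), copy
    number ~ Normal(1, 0.15) truncated at 0 with amplification probability
    ``p_amp`` and amplified values Uniform[2, 6].
    """

    n_samples: int
    genes: tuple[tuple[str, float], ...]  # (gene, mutation frequency)
    drugs: tuple[str, ...]
    measures: tuple[str, ...] = ("AUC", "EC50", "LFC")
    auc_mu: float = 1.0
    auc_sigma: float = 0.15
    ec50_log_mu: float = 0.0
    ec50_log_sigma: float = 1.0
    lfc_mu: float = 0.0
    lfc_sigma: float = 1.0
    cnv_mu: float = 1.0
    cnv_sigma: float = 0.15
    p_amp: float = 0.02
    amp_range: tuple[float, float] = (2.0, 6.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or not self.genes or not self.drugs:
            raise ValueError("cohort needs positive sample, gene, and drug counts")
        for g, f in self.genes:
            if not 0.0 < f < 1.0:
                raise ValueError(f"mutation frequency for {g} must be in (0, 1)")
        for s in (self.auc_sigma, self.ec50_log_sigma, self.lfc_sigma, self.cnv_sigma):
            if s <= 0:
                raise ValueError("scale parameters must be positive")
        if not 0.0 <= self.p_amp < 1.0:
            raise ValueError("p_amp must be in [0, 1)")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.genes]


def _truncated_normal(rng, mu, sigma, size):
    """Normal(mu, sigma) conditioned on > 0 (redraw rejection)."""
    out = rng.normal(mu, sigma, size=size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        bad = out <= 0
    return out


def _check_truth(spec: CohortSpec, truth: SyntheticTruth):
    genes = set(spec.gene_ids)
    drugs = set(spec.drugs)
    measures = set(spec.measures)
    for eff in (*truth.snv_effects, *truth.cnv_effects):
        if eff.gene not in genes:
            raise ValueError(f"effect references unknown gene {eff.gene!r}")
        if eff.drug not in drugs:
            raise ValueError(f"effect references unknown drug {eff.drug!r}")
        if eff.measure not in measures:
            raise ValueError(f"effect references unplanned measure {eff.measure!r}")


def _base_scale(spec: CohortSpec, measure: str) -> float:
    """Pooled SD of the base model on the analysis scale."""
    return {
        "AUC": spec.auc_sigma,
        "EC50": spec.ec50_log_sigma,
        "IC50": spec.ec50_log_sigma,
        "LFC": spec.lfc_sigma,
    }[measure]


def generate_cohort(spec: CohortSpec, truth: SyntheticTruth | None = None):
    """Draw a cohort; deterministic given (spec, truth).

    Responses are base-model draws plus the planted SNV shifts for each
    sample's mutated effect genes and β·(CNV−1) for planted CNV effects,
    with EC50/IC50 effects applied on the log scale before exponentiation.
    Returns (MutationMatrix, CopyNumberMatrix, ResponseTable, truth).
    """
    truth = truth or SyntheticTruth.empty()
    _check_truth(spec, truth)
    rng = np.random.default_rng(spec.seed)
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]
    genes = spec.gene_ids

    freqs = np.array([f for _, f in spec.genes])
    calls = (rng.random((spec.n_samples, len(genes))) < freqs).astype(np.int8)
    mut = MutationMatrix(pd.DataFrame(calls, index=samples, columns=genes))

    cn = _truncated_normal(rng, spec.cnv_mu, spec.cnv_sigma,
                           (spec.n_samples, len(genes)))
    amp = rng.random((spec.n_samples, len(genes))) < spec.p_amp
    cn[amp] = rng.uniform(*spec.amp_range, size=int(amp.sum()))
    cnv = CopyNumberMatrix(pd.DataFrame(cn, index=samples, columns=genes))

    snv_by_key: dict[tuple[str, str], list[SnvEffect]] = {}
    for eff in truth.snv_effects:
        snv_by_key.setdefault((eff.drug, eff.measure), []).append(eff)
    cnv_by_key: dict[tuple[str, str], list[CnvEffect]] = {}
    for eff in truth.cnv_effects:
        cnv_by_key.setdefault((eff.drug, eff.measure), []).append(eff)

    gidx = {g: i for i, g in enumerate(genes)}
    records = []
    for drug in spec.drugs:
        for measure in spec.measures:
            if measure == "AUC":
                base = _truncated_normal(rng, spec.auc_mu, spec.auc_sigma,
                                         spec.n_samples)
            elif measure in ("EC50", "IC50"):
                base = rng.normal(spec.ec50_log_mu, spec.ec50_log_sigma,
                                  spec.n_samples)  # log scale
            elif measure == "LFC":
                base = rng.normal(spec.lfc_mu, spec.lfc_sigma, spec.n_samples)
            else:  # pragma: no cover - guarded by CohortSpec/io enums
                raise ValueError(f"unsupported measure {measure!r}")

            shift = np.zeros(spec.n_samples)
            sd = _base_scale(spec, measure)
            for eff in snv_by_key.get((drug, measure), ()):
                sign = _SENSITIZING_SIGN[measure]
                if eff.direction == "resistant":
                    sign = -sign
                shift += sign * eff.delta * sd * calls[:, gidx[eff.gene]]
            for eff in cnv_by_key.get((drug, measure), ()):
                shift += eff.beta * (cn[:, gidx[eff.gene]] - 1.0)

            vals = base + shift
            if measure in ("EC50", "IC50"):
                vals = np.exp(vals)
            elif measure == "AUC":
                vals = np.maximum(vals, 0.0)  # respect the AUC >= 0 contract
            records.append(
                pd.DataFrame(
                    {
                        "sample_id": samples,
                        "drug": drug,
                        "measure": measure,
                        "value": vals,
                    }
                )
            )
    resp = ResponseTable(pd.concat(records, ignore_index=True))
    return mut, cnv, resp, truth


def make_null_spec(n_samples: int, n_genes: int, n_drugs: int, seed: int):
    """Convenience null cohort: driver-like mutation frequencies drawn
    log-uniform in [0.05, 0.3], default response models, no planted effects."""
    if n_samples < 1 or n_genes < 1 or n_drugs < 1:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)
    freqs = np.exp(rng.uniform(np.log(0.05), np.log(0.3), size=n_genes))
    genes = tuple((f"G{i:03d}", float(f)) for i, f in enumerate(freqs))
    drugs = tuple(f"D{j:02d}" for j in range(n_drugs))
    return CohortSpec(n_samples=n_samples, genes=genes, drugs=drugs, seed=seed), \
        SyntheticTruth.empty()


def panel_for_spec(spec: CohortSpec, cancer_code: str = "SYN") -> CancerPanel:
    """Panel treating every simulated gene as a driver and every drug as
    screened — the natural panel for a generated cohort."""
    return CancerPanel(
        cancer_code=cancer_code,
        drugs=spec.drugs,
        driver_genes=tuple(spec.gene_ids),
        measures=spec.measures,
    )


def write_cohort(mut, cnv, resp, outdir) -> dict[str, str]:
    """Write the three standard input files; round-trips through cohort I/O."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": str(outdir / "mutations.csv"),
        "copy_number": str(outdir / "copy_number.csv"),
        "responses": str(outdir / "responses.csv"),
    }
    write_matrix(mut, paths["mutations"])
    write_matrix(cnv, paths["copy_number"])
    write_response_table(resp, paths["responses"])
    return paths
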