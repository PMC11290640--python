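"""End-to-end panel runs: transform → compare → call → map → report.

Each cancer panel is processed independently, measure by measure: a
transform is fitted to the panel's pooled values of that measure, the
pooled driver-set comparison and per-gene comparisons are run, the strict
and relaxed consensus rules produce biomarker calls, and a signed
significance map is assembled.  The CNV arm mirrors this with max-driver
bin summaries, per-gene associations, and correlation maps.  All tables go
under the run's output directory; a JSON report summarizes counts, calls,
and the file manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import io as cio
from . import snv as csnv
from . import cnv as ccnv
from .maps import build_map, export_map, signed_significance
from .snv import DRIVER_SET, ScreeningRule
from .transform import select_and_apply_transform

__all__ = ["RunConfig", "RunReport", "run_snv_screen", "run_cnv_screen", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    mutations: object = None  # path or MutationMatrix
    copy_number: object = None  # path or CopyNumberMatrix
    responses: object = None  # path or ResponseTable
    panels: object = None  # path or list[CancerPanel]
    outdir: str = "results/run"
    seed: int = 0
    use_transform: bool = True  # raw-scale switch
    cnv_bin_mode: str = "nearest"
    make_maps: bool = True
    images: bool = False


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig(**raw)


@dataclass
class PanelMeasureReport:
    panel: str
    measure: str
    transform_family: str | None = None
    transform_lambda: float | None = None
    n_samples_joined: int = 0
    comparisons_evaluated: int = 0
    comparisons_not_evaluable: int = 0
    strict_calls: dict = field(default_factory=dict)  # gene -> drug list
    relaxed_calls: dict = field(default_factory=dict)
    calls_per_category: dict = field(default_factory=dict)  # {1,2,3+} -> genes
    driver_set_significant_drugs: list = field(default_factory=list)
    files: list = field(default_factory=list)


@dataclass
class RunReport:
    kind: str
    seed: int
    panels: list = field(default_factory=list)  # PanelMeasureReport dicts
    cross_cancer_span: dict = field(default_factory=dict)
    manifest: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=1, default=str)
        if path:
            Path(path).write_text(s)
        return s


def _resolve_inputs(cfg: RunConfig, need_cnv: bool = False):
    mut = cfg.mutations
    if isinstance(mut, (str, Path)):
        mut = cio.read_mutation_matrix(mut)
    resp = cfg.responses
    if isinstance(resp, (str, Path)):
        resp = cio.read_response_table(resp)
    panels = cfg.panels
    if isinstance(panels, (str, Path)):
        panels = cio.load_panel_config(panels)
    cnv = cfg.copy_number
    if need_cnv:
        if cnv is None:
            raise ValueError("CNV screening requires a copy-number matrix in the config")
        if isinstance(cnv, (str, Path)):
            cnv = cio.read_copy_number_matrix(cnv)
    return mut, cnv, resp, panels


def _fit_transform(cfg, resp, panel, measure, outdir, report):
    if not cfg.use_transform:
        return None
    pool = resp.pool(panel.drugs, measure)
    try:
        tspec, _ = select_and_apply_transform(measure, pool)
    except ValueError as exc:
        logger.warning("panel %s/%s: %s; proceeding on the raw scale",
                       panel.cancer_code, measure, exc)
        return None
    report.transform_family = tspec.family
    report.transform_lambda = tspec.lam
    tpath = outdir / f"{panel.cancer_code}_{measure}_transform.json"
    tpath.write_text(tspec.to_json())
    report.files.append(str(tpath))
    return tspec


def run_snv_screen(cfg: RunConfig) -> RunReport:
    """Run the SNV arm for every (panel, measure); deterministic given config."""
    mut, _, resp, panels = _resolve_inputs(cfg)
    resp, mut, _ = cio.align_samples(resp, mut)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = RunReport(kind="snv", seed=cfg.seed)
    strict_calls_by_panel: dict[str, list] = {}

    for panel in panels:
        panel_strict: list = []
        for measure in panel.measures:
            rep = PanelMeasureReport(panel=panel.cancer_code, measure=measure,
                                     n_samples_joined=len(mut.sample_ids))
            tspec = _fit_transform(cfg, resp, panel, measure, outdir, rep)

            driver_part = csnv.partition_by_driver_set(mut, panel.driver_genes)
            driver_comps = [
                csnv.compare_groups(resp, driver_part, drug, measure, tspec,
                                    target=DRIVER_SET)
                for drug in panel.drugs
            ]
            rep.driver_set_significant_drugs = [
                c.drug for c in driver_comps
                if c.evaluable and csnv.passes_rule(c.p_t, c.p_w, c.p_m,
                                                    ScreeningRule("strict"))
            ]

            comps = csnv.screen_panel_genes(mut, resp, panel, measure, tspec)
            rep.comparisons_evaluated = sum(c.evaluable for c in comps)
            rep.comparisons_not_evaluable = sum(not c.evaluable for c in comps)

            table = csnv.comparisons_to_frame(driver_comps + comps)
            tsv = outdir / f"{panel.cancer_code}_{measure}_snv_comparisons.tsv"
            table.to_csv(tsv, sep="\t", index=False)
            rep.files.append(str(tsv))

            strict = csnv.call_biomarkers(comps, ScreeningRule("strict"))
            relaxed = csnv.call_biomarkers(comps, ScreeningRule("relaxed"))
            rep.strict_calls = {c.gene: list(c.affected_drugs) for c in strict}
            rep.relaxed_calls = {c.gene: list(c.affected_drugs) for c in relaxed}
            cats: dict[str, list] = {"1": [], "2": [], "3+": []}
            for call in strict:
                cats[call.category].append(call.gene)
            rep.calls_per_category = cats
            panel_strict.extend(strict)

            if cfg.make_maps:
                cells = {}
                for c in comps:
                    if c.evaluable and c.p_t > 0:
                        cells[(c.target, c.drug)] = signed_significance(c)
                if len({g for g, _ in cells}) >= 2 and len({d for _, d in cells}) >= 2:
                    smap = build_map(cells, source="snv_p", measure=measure)
                    rep.files += export_map(
                        smap, outdir / f"{panel.cancer_code}_{measure}_snv_map",
                        image=cfg.images,
                    )
            run.panels.append(asdict(rep))
            run.manifest += rep.files
        strict_calls_by_panel[panel.cancer_code] = panel_strict

    run.cross_cancer_span = csnv.cross_cancer_span(strict_calls_by_panel)
    run.to_json(outdir / "report_snv.json")
    run.manifest.append(str(outdir / "report_snv.json"))
    return run


def run_cnv_screen(cfg: RunConfig) -> RunReport:
    """Run the CNV arm: max-driver bins, summaries, associations, maps."""
    mut, cnv, resp, panels = _resolve_inputs(cfg, need_cnv=True)
    resp, cnv, _ = cio.align_samples(resp, cnv)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = RunReport(kind="cnv", seed=cfg.seed)

    for panel in panels:
        groups = ccnv.max_driver_cnv_groups(cnv, panel.driver_genes,
                                            mode=cfg.cnv_bin_mode)
        for measure in panel.measures:
            rep = PanelMeasureReport(panel=panel.cancer_code, measure=measure,
                                     n_samples_joined=len(cnv.sample_ids))
            tspec = _fit_transform(cfg, resp, panel, measure, outdir, rep)

            summaries = []
            for drug in panel.drugs:
                summary, tau = ccnv.cnv_group_response_summary(groups, resp,
                                                               drug, measure)
                summary.insert(0, "drug", drug)
                summary["trend_tau"] = tau
                summaries.append(summary)
            import pandas as pd

            sum_tsv = outdir / f"{panel.cancer_code}_{measure}_cnv_groups.tsv"
            pd.concat(summaries, ignore_index=True).to_csv(sum_tsv, sep="\t",
                                                           index=False)
            rep.files.append(str(sum_tsv))

            assocs = []
            for gene in panel.driver_genes:
                if gene not in cnv.df.columns:
                    continue
                for drug in panel.drugs:
                    assocs.append(
                        ccnv.cnv_gene_association(cnv, resp, gene, drug,
                                                  measure, tspec)
                    )
            rep.comparisons_evaluated = sum(a.evaluable for a in assocs)
            rep.comparisons_not_evaluable = sum(not a.evaluable for a in assocs)
            assoc_tsv = outdir / f"{panel.cancer_code}_{measure}_cnv_associations.tsv"
            ccnv.associations_to_frame(assocs).to_csv(assoc_tsv, sep="\t",
                                                      index=False)
            rep.files.append(str(assoc_tsv))

            if cfg.make_maps:
                cells = {(a.gene, a.drug): a.p_cor for a in assocs if a.evaluable}
                if len({g for g, _ in cells}) >= 2 and len({d for _, d in cells}) >= 2:
                    smap = build_map(cells, source="cnv_r", measure=measure)
                    rep.files += export_map(
                        smap, outdir / f"{panel.cancer_code}_{measure}_cnv_map",
                        image=cfg.images,
                    )
            run.panels.append(asdict(rep))
            run.manifest += rep.files

    run.to_json(outdir / "report_cnv.json")
    run.manifest.append(str(outdir / "report_cnv.json"))
    return run
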