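# pgxscreen

Biomarker screening for cell-line pharmacogenomics: which driver-gene
mutations shift a drug's response?

Large pooled screens measure drug response (AUC of the viability curve,
EC50/IC50 concentrations, or log2 fold-change at a fixed dose) across
hundreds of cancer cell lines whose genomes are characterized by binary
SNV calls and relative copy numbers.  `pgxscreen` implements a
transparent, test-driven pipeline over such cohorts:

1. **Normalization** — each (panel, measure) pool is power-transformed
   toward normality: Box-Cox λ̂ by profile maximum likelihood for
   nonnegative measures (identity if |λ̂−1| ≤ 0.25, log if |λ̂| ≤ 0.25,
   else Box-Cox), Yeo-Johnson for signed measures, then mean-centering.
2. **Group comparison** — for every (gene, drug, measure), mutated vs
   unmutated lines are compared with the Welch t-test, the
   Mann-Whitney-Wilcoxon test (exact for small untied groups), and the
   Brown–Mood median test, giving a p-value triple (p.t, p.w, p.m).
3. **Consensus calling** — a gene is a biomarker for a drug when
   p.t, p.w, p.m < 0.05 simultaneously or min(p) < 0.01 (strict), or when
   at least two of the three are < 0.05 (relaxed).  Calls are categorized
   by affected-drug count {1, 2, 3+} and by cross-cancer span.
4. **Copy-number arm** — samples grouped by the integer-binned maximum
   driver copy number {1, 2, 3, 4+} with per-bin summaries and trend
   checks, plus continuous CNV-response correlations (P.cor, S.rho,
   K.tau) and OLS/Huber fits per gene.
5. **Sensitivity maps** — gene × drug matrices of signed reciprocal
   significance (±1/p.t, positive = sensitizing) or CNV Pearson
   correlations, hierarchically clustered (complete linkage, Euclidean).

A synthetic-cohort generator with planted ground-truth effects makes the
whole pipeline testable end to end.  See `docs/methods.md` for the full
statistical account.

## Worked example

The six published gene × drug p-value triples from a BRCA IC50 validation
screen, run through the consensus rule
(`python analysis/06_validation_worked_example.py`):

```
  Gene           Drug   p.t   p.w   p.m  No. mutated  No. unmutated  strict  relaxed
 FOXA1     paclitaxel 0.011 0.037 0.157            2            937   False     True
  BAP1     paclitaxel 0.011 0.014 0.068           15            924   False     True
 NTRK3      tamoxifen 0.025 0.055 0.014            6            932   False     True
 ERBB2    gemcitabine 0.031 0.032 0.019           15            927    True     True
  ETV6      tamoxifen 0.053 0.034 0.033            8            930   False     True
PIK3CA 5-fluorouracil 0.085 0.049 0.009           94            855    True     True

strict biomarkers (2): ERBB2, PIK3CA
relaxed biomarkers (6): FOXA1, BAP1, NTRK3, ERBB2, ETV6, PIK3CA
```

ERBB2 passes strictly because all three tests agree below 0.05; PIK3CA
because its median-test p (0.009) clears the 0.01 strong-evidence bar on
its own.  FOXA1 shows how the strict rule guards against a single
discordant test: two p-values below 0.05 are relaxed-grade evidence only.

On a simulated 300-line cohort with six planted SNV effects
(`analysis/01_simulate_cohort.py` then `analysis/03_screen_snv.py`), the
strict screen recovers all six, e.g.:

```
SYN_SKCM/EC50 (log transform, 50 comparisons):
  driver-set significant drugs: ['dabrafenib']
  strict: BRAF -> ['dabrafenib']
  strict: NRAS -> ['trametinib']
  categories: {'1': ['BRAF', 'NRAS']}
...
recovered 6/6 planted effects; 3 additional strict calls (expected ~3% of null
comparisons under the consensus rule)
```

## Command line

```sh
pgxscreen simulate --n-samples 300 --n-genes 30 --n-drugs 10 --seed 1 --outdir cohort/
pgxscreen screen-snv --mutations cohort/mutations.csv \
    --responses cohort/responses.csv --panels cohort/panels.yaml --outdir run/
pgxscreen screen-cnv --config run.yaml
pgxscreen report run/report_snv.json
```

`configs/panels_ccle.yaml` ships the seven-cancer panel configuration
(drugs, Cancer Gene Census driver genes, measures) used throughout the
examples.  The numbered scripts under `analysis/` walk the full study on
a simulated cohort: simulate → distribution/transform checks → SNV screen
→ CNV screen → sensitivity maps → published worked example, writing
tables under `results/`.

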