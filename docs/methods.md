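# Methods

`pgxscreen` screens binary driver-gene SNV calls and relative copy numbers
against cell-line drug-response measures to nominate predictive biomarkers.
This note records the statistical procedure, the choices made where the
design was open, and what the synthetic validation does and does not show.

## Data model

Three inputs per cohort: a binary sample × gene SNV matrix (1 = the gene
carries at least one variant in that line), a nonnegative sample × gene
relative copy-number matrix (diploid-neutral ≈ 1, amplification > 1), and a
long-format response table keyed by (sample, drug, measure) with measures
AUC, EC50, LFC, and IC50.  Cancer panels name each cancer's drugs, Cancer
Gene Census driver genes, and measures.  Sample identifiers are opaque
strings; inputs are joined by exact match and samples missing from any
required input are dropped with a logged count (screen and genomic releases
rarely share a full cell-line roster, and no finer matching rule is
assumed).

## Response normalization

Group tests downstream assume rough normality, so each (panel, measure)
pool — the measure's values pooled across the panel's drugs — is
transformed once and the fitted mapping is applied uniformly:

* nonnegative measures (AUC, EC50, IC50): the Box-Cox λ is estimated by
  profile maximum likelihood over λ ∈ [−2, 2] (0.01 grid plus bounded
  refinement; deterministic).  |λ̂ − 1| ≤ 0.25 keeps the identity, |λ̂| ≤
  0.25 selects a plain log, otherwise Box-Cox(λ̂) is applied.  The ±0.25
  proximity band cleanly separates "λ close to 1" (AUC-like) from "λ close
  to 0" (EC50-like) pools.
* measures with negative values (LFC): Yeo-Johnson at the MLE λ̂.

The transformed pool is mean-centered, and the spec (family, λ, center) is
serialized next to the outputs so reruns are bit-reproducible.  Pools under
20 values are refused — λ is too unstable there and raw-scale analysis is
the honest alternative (a raw-scale switch exists for exactly that case).

Normality is reported with a one-sample Kolmogorov-Smirnov check against a
normal with the pool's estimated mean and SD, with the p-value from the
asymptotic Kolmogorov distribution at √n·D.  Because the null parameters
are estimated from the same data, this p-value is anti-conservative (the
Lilliefors effect); it is reported as a descriptive index, not used for
calling.

**λ identifiability.**  The Box-Cox λ is only weakly identified when the
pool's coefficient of variation is small: λ and the scale parameter are
nearly confounded, and at cv = 0.15, n = 500 the sampling SD of λ̂ is ≈
0.24.  The λ-recovery validation therefore uses pools where λ is
identified — lognormal pools (cv ≈ 1.3) and positive near-normal pools at
cv = 0.3 (sd(λ̂) ≈ 0.08) — while the cohort simulator keeps AUC at cv =
0.15, the screen-like condition.  The identity-transform decision for such
low-cv pools is exercised on panel-pooled values (samples × drugs ≥ 3000
values), where |λ̂ − 1| ≤ 0.25 is stable.  Note that when strong effects
are planted, a pooled AUC distribution is a shifted mixture and the
selected family can legitimately move off the identity; the screen is
unaffected because the transform is monotone.

## Group comparisons and the consensus rule

For each (gene, drug, measure) the cohort splits into mutated vs unmutated
lines (for the pooled driver-set analysis: any driver mutated vs none).
Three two-sample tests are run on the transformed values:

* **Welch t** — t = (x̄₁−x̄₂)/√(s₁²/n₁+s₂²/n₂) with Welch–Satterthwaite
  degrees of freedom; two-sided.
* **Mann-Whitney-Wilcoxon** — exact null distribution of U (computed by
  the Gaussian-binomial counting recurrence, cached per group-size pair)
  when n₁, n₂ ≤ 50 and the pooled sample is tie-free; otherwise the normal
  approximation with tie and continuity corrections.
* **Brown–Mood median test** — pooled values dichotomized at the common
  median (strictly above vs at-or-below), 1-df Pearson chi-square on the
  2×2 table without continuity correction; a Yates flag is exposed.  When
  all pooled values fall on one side the comparison is flagged degenerate
  with p = 1.  The uncorrected convention follows the asymptotic score
  character of the procedure; note that with continuous data and equal
  groups of 50 its exact level at α = 0.05 is 0.0713 (hypergeometric
  enumeration with fixed 50/50 margins), i.e. mildly anti-conservative —
  the consensus rule, which demands agreement across tests, absorbs this.

All tests are two-sided.  Groups need at least 2 response values each;
smaller comparisons are reported as not-evaluable rather than dropped
silently (published validation screens include comparisons with as few as
2 mutated lines, so no larger floor is imposed).

A gene is called a biomarker for a drug under the **strict** consensus
rule when all three p-values are < 0.05 or any one is < 0.01, and under
the **relaxed** rule when at least two of the three are < 0.05.  The
threshold ladder 0.01/0.05/0.1 marks strong/moderate/weak evidence; the
0.1 rung only annotates "weak evidence" in reports and never calls.  No
multiple-testing correction is applied by default, matching the raw
threshold ladder of the screening procedure; a Benjamini–Hochberg flag
exists for users and is clearly a deviation when enabled.  Called genes
are categorized by affected-drug count into {1, 2, 3+}, and a gene's
cross-cancer span is the number of panels in which it has at least one
call.

Under the null the three tests are strongly correlated, so the strict
consensus call rate per comparison is well below the nominal 5% — about
3% in 5000-replicate simulations, within the [0.005, 0.08] band expected
for correlated tests.

## Copy-number analyses

Relative copy numbers are integer-binned either by rounding half away
from zero (default, the "adjust to integers" convention) or by rounding
up (the dichotomization used for near-neutral two-group splits; both
conventions appear in practice and both are exposed).  Samples are
grouped by the binned maximum copy number over the panel's drivers into
{1, 2, 3, 4+}; bin 0 (deletion territory) is kept as its own label but
excluded from trend summaries, which report per-bin n/mean/quartiles and
a Kendall-tau trend check.  Per-gene association uses the *continuous*
copy number against the transformed response: Pearson, Spearman, and
tie-adjusted Kendall tau-b coefficients plus OLS and Huber-M (c = 1.345,
IRLS to 1e−8, ≤ 50 iterations) fits.  Constant copy-number vectors yield
not-evaluable records.

## Sensitivity maps

Each evaluable (gene, drug) comparison maps to a signed score: the
reciprocal of the Welch-t p-value (floored at 1e−300 to stay finite),
positive when the mutation is sensitizing — lower EC50/IC50, higher AUC,
or lower LFC in the mutated group — negative for resistance, zero on an
exact mean tie.  The Welch p alone feeds the maps; the other two tests
gate calling, not scoring.  The LFC direction (stronger kill = lower
fold-change = sensitizing) is a package convention and configurable.
CNV maps instead hold the Pearson correlation of continuous copy number
with response.  Rows and columns are ordered by agglomerative clustering
(complete linkage, Euclidean distance; ties broken by input order);
missing cells are imputed as 0 for clustering only and exported as NA.
For rendering, |score| is clipped at 1/0.001 — reciprocal scores are
heavy-tailed — while stored values are unclipped.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: AUC ~
Normal(1, 0.15) truncated positive, EC50 = exp(Normal(0, 1)), LFC ~
Normal(0, 1), copy number ~ Normal(1, 0.15) truncated positive with
amplification probability 0.02 and amplified values Uniform[2, 6], and
independent Bernoulli SNVs at gene-specific frequencies (driver-like
defaults log-uniform in [0.05, 0.3]).  Planted SNV effects are additive
on the analysis scale in pooled-SD units (EC50/IC50 effects act on the
log scale), so δ = 1 moves the mutated group one SD in the sensitive
direction and power is analytically checkable against the t-test power
function; CNV effects are linear slopes per copy above neutral.
Everything is deterministic given the seed.

What the generator does *not* model: co-mutation structure between genes,
chromosome/segment-level copy-number correlation, dose-response curve
fitting noise (AUC/EC50 are drawn directly), or panel-specific response
scales.  Passing recovery tests therefore demonstrate the statistical
machinery — calibration, power, sign conventions — not robustness to the
correlation structure of real screens.

## Validation study sizes

The shipped validation runs use: 5000 null replicates at n = 50/50 for
test calibration; 100 replicates of n = 500 pools for λ recovery; 200
replicates of n = 300 cohorts (mutation frequency 0.3, δ = 1.5) for
end-to-end recovery, with the CNV arm's slope chosen so the population
Pearson r is ≈ 0.3; and the six printed validation-screen p-value triples
for the consensus-rule worked example.  The full set runs in well under a
minute on one core.

## Known limitations

* The KS normality p-value ignores parameter estimation (anti-conservative).
* The uncorrected median test is mildly anti-conservative at moderate
  equal group sizes (exact level ≈ 0.071 at 50/50); use the Yates flag if
  a conservative marginal test is required.
* Whether published group tests ran on transformed or raw values is
  ambiguous; the pipeline defaults to transformed with a raw-scale switch.
* Exact-string sample joining cannot recover lines renamed between
  releases.
* No multiple-testing correction by default: the consensus rule controls
  the per-comparison rate, not the family-wise rate across a panel.
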