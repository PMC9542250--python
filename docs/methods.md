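# Methods

This note documents the statistical procedures implemented in
`cerna_moml`, the defaults and why they were chosen, what the synthetic
cohorts do and do not emulate, and the numerical decisions that matter
for reproducing results.

## Differential expression

Raw counts (features × samples, tumour/normal labels) pass through:

- **Low-count filter.** A feature is dropped when its log₂-CPM (prior
  count 0.5, raw library sizes) is below 1 in *strictly more than* half
  the samples. The strict reading keeps a feature expressed in exactly
  half the samples.
- **TMM normalization.** Per-sample scale factors are trimmed means of
  M-values against a reference column (the sample whose CPM upper
  quartile is closest to the mean upper quartile), trimming 30% of
  M-values and 5% of A-values, with inverse delta-method binomial
  variances as weights; factors are rescaled to geometric mean one.
  The trim fractions are the method's classical defaults.
- **voom-style transform.** log₂((count + 0.5)/(lib·factor + 1)·10⁶).
  Precision weights come from a LOWESS fit (span 0.5) of √(residual SD)
  on mean log₂ count under the two-group model, evaluated per
  observation at its fitted log-count and raised to the −4 power on the
  SD scale. With fewer than 10 features the trend is meaningless and
  weights fall back to 1 with a warning; `weight_mode="none"` disables
  weighting entirely.
- **Moderated t.** Per-feature weighted least squares on the group
  indicator; residual variances s²_g (d_g = n − 2 df) are shrunk to
  s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), with (d₀, s₀²) estimated by
  method of moments on log s² under the scaled-F hierarchical model
  (digamma/trigamma matching; the trigamma inverse is solved by Newton
  iteration). t = logFC/(s̃·SE), referred to a t distribution with
  d₀ + d_g df. d₀ can be forced to 0 (ordinary t) or ∞ (complete
  pooling), which the tests use as oracle limits.
- **Selection.** |log₂FC| > 1 and Benjamini–Hochberg FDR < 0.01, both
  strict, split by feature class (mRNA / lncRNA / miRNA). BH is used
  wherever an "adjusted p" or "FDR" appears in the pipeline.

This stage is a compact reimplementation of the standard count stack; it
is not expected to replicate edgeR/limma numerically (different LOWESS,
no quantile/array weights, no contrasts).

## Per-gene regulator models

For each DE mRNA the design holds the gene's own CNA value, its own DM β
value, the tumour expression of its candidate miRNAs (from the
interaction tables, restricted to DE miRNAs) and of its candidate TFs
(not restricted to DE TFs, since TF regulation need not show as
differential expression of the TF itself). lncRNA designs hold candidate
miRNA columns only; this is asserted structurally. Columns are
standardized to mean 0, SD 1, the response is centred (absorbing the
intercept unpenalized), and samples with an NA in any design column are
dropped for that model only.

**Penalty parametrization.** The objective is
(1/2n)‖y − Xβ‖² + λ‖β‖₁, the coordinate-descent convention, under which
the all-zero solution appears exactly at λ_max = max|Xᵀy|/n. The grid is
100 log-spaced values from λ_max down to 10⁻³λ_max.

**Solver.** Pathwise coordinate descent on the Gram system
(G = XᵀX, Xᵀy) with warm starts along the descending grid and covariance
updates, so one sweep costs O(p²) independent of n; the inner loop is
JIT-compiled. Per-fold training Gram matrices are obtained by
subtracting the held-out block from the full Gram. The solver is
validated against scikit-learn's `lasso_path` to < 10⁻⁸ in the tests.

**Cross-validation and the λ rule.** 10-fold CV on the fixed grid.
`fit_lasso_cv` returns the penalty minimizing mean held-out squared
error (exact ties to the larger penalty). Inside stability selection,
however, the per-run penalty uses the **one-standard-error rule** (the
largest λ whose mean CV error is within one SE — SD across folds /√k —
of the minimum). Rationale, measured on planted designs: the runs share
the data and only reshuffle folds, so the CV-minimum λ is nearly
constant across runs and sits deep in the flat region of the CV curve
where weakly correlated decoys carry tiny non-zero coefficients in
essentially every run; selection frequency then cannot separate decoys
from true regulators (decoys retained at count ≈ 100). With the 1-SE
rule, true regulators (entry λ ≈ 0.42 at |β| = 0.5, σ = 0.2, n = 100)
are always retained while decoys (entry λ ≤ 0.064) drop to ≤ 5%
retention.

**Stability selection.** 100 refits with reshuffled folds; a predictor
is retained when non-zero in strictly more than 75 runs. The full-data
path is computed once per gene since it is invariant across runs.

**Bootstrap confirmation.** Case-resampling bootstrap (B = 1000,
percentile CI at level 0.95) of the LASSO refit at the full-data λ*,
restricted to the retained predictors; a predictor is significant when
its CI excludes zero. Because the L1 penalty zeroes a coefficient in a
fraction of resamples, the percentile CI of a spurious predictor touches
zero, which removes the occasional pure-noise survivor of the selection
stage. Retained miRNAs with a *positive* confirmed coefficient are
excluded from the gene's miRNA set by default
(`require_negative_mirna`): the sponge mechanism assumes repression.

## ceRNA pair calling

Candidates are unordered target pairs with ≥ 1 shared significant miRNA;
classes are mRNA–mRNA and lncRNA–mRNA (lncRNA–lncRNA pairs are not
considered). Three conjunctive filters, evaluated cheapest first
(the passed set does not depend on the order):

1. **Pearson** r > 0.40 (strict), on tumour expression.
2. **Hypergeometric shared-miRNA test**: upper-tail
   P(X ≥ k) for X ~ Hypergeom(N, |set_A|, |set_B|), p < 0.05. The
   population N is the number of distinct miRNAs appearing in any
   target's significant regulator set of the cohort — the universe
   actually available to be shared (configurable).
3. **mscor**: cor(x,y) − pcor(x,y | M), M the expression of *all* shared
   miRNAs. Partial correlation is computed both by residual regression
   on [1, Z] and by the precision-matrix formula (the two agree to
   10⁻¹⁰ and serve as mutual oracles); collinear conditioning columns
   are dropped with a warning. With |M| = 1 this is the single-miRNA
   sensitivity correlation (scor); the reported `scor` field is the mean
   over single-miRNA values. Significance is a one-sided permutation
   test: the rows of M are permuted jointly n_perm times (x and y stay
   fixed, preserving their correlation while destroying the
   miRNA–target coupling); p = (1 + #{mscor_perm ≥ observed})/(1 + n_perm).
   The permutation recomputation uses the Schur-complement identity —
   the M-block correlation matrix is permutation-invariant, so only the
   cross-correlation vectors are recomputed — making the test O(n_perm·m²)
   after one pass over the data. p-values are BH-adjusted across all
   pairs that reached this stage (per cohort); adjusted p < 0.05 passes.

The permutation null was chosen as a fully specified, dependency-free
construction; it is calibrated (empirical rejection at 0.05 within
[0.03, 0.07] over 500 independence replicates) but is not the
covariance-simulation null of the original sparse-partial-correlation
package, whose p-values it should not be expected to reproduce.

## Cross-cohort intersection

Passed pairs are keyed `idA_idB` with the lexicographically smaller
Ensembl-style id (version suffixes stripped at ingestion) first, and
compiled into a one-way frequency table. A pair with frequency equal to
the cohort count is shared across all cohorts; frequency 2 or 3 assigns
it to the respective combination. Both "exactly this combination"
(which partitions the pairs and is the default presentation) and
"at least this combination" tabulations are emitted, with pair counts
and unique-gene counts.

## Survival screening and enrichment

Per gene and cohort, tumour samples are split at the cohort median of
the gene's expression (ties at the median go to low; quartile splits are
available). Low vs high groups are compared with the log-rank test
(1 df), Kaplan–Meier curves are product-limit estimates, and the hazard
ratio of high vs low comes from a univariate Cox proportional-hazards
fit with Efron tie handling (appropriate for the heavily tied
dichotomized covariate); fits with |log HR| > 10 or convergence warnings
are flagged as diverged (monotone likelihood). A gene shared by a cohort
combination is *combination-significant* only when its log-rank p is
below 0.05 in **every** member cohort — a conjunction, not a meta-analysis.
The survival endpoint is whatever the clinical table encodes (overall
survival assumed); the expression cutpoint and α are configurable.

Gene-set enrichment is an upper-tail hypergeometric test of a gene list
against each GMT set over an explicit, user-supplied universe, BH
adjusted across sets. No ontology content ships with the package.

## The synthetic cohorts

`simulate_cohort` generates, from one seed feeding named sub-streams
(wiring / expression / counts / survival, so stages can be re-simulated
independently):

- **Continuous tumour expression** directly on the log scale:
  mRNA_g = β_cna·CNA_g + β_dm·DM_g + Σ β_mir·miRNA + β_tf·TF + ε,
  lncRNA = Σ β_mir·miRNA + ε, ε ~ N(0, noise_sd). Planted pairs load on
  the same `mirnas_per_pair` miRNAs (disjoint sets across pairs while
  the miRNA pool lasts). Defaults: β_cna = 0.5, β_dm = −0.5
  (methylation represses), β_tf = 0.5, β_mirna = −0.5, noise_sd = 0.2,
  n_tumour = 100, 50 mRNAs / 10 lncRNAs / 30 miRNAs / 10 TFs, 10 pairs
  sharing 3 miRNAs each. Every gene also receives decoy miRNA (5) and
  TF (1) candidate edges with true coefficient zero, providing
  false-positive pressure.
- **Counts** for the DE stage, drawn independently of the continuous
  layer (the pipeline likewise calls DE on counts but models normalized
  expression): negative binomial with dispersion 0.2, lognormal baseline
  means (median ≈ 250), and a ±nb_mean_log2fc (default 2) tumour/normal
  log₂ fold change on the DE features (all pipeline-relevant features
  plus a 30% random subset of the rest, alternating sign).
- **CNA** ~ N(0,1); **DM β** = logistic(N(0,1)), always in [0, 1].
- **Survival**: exponential event times with baseline rate 0.1 and log
  hazard ratio `surv_log_hr` (default 1.0) for samples above the median
  expression of the first planted gene; independent censoring with
  probability `censor_rate` (default 0.3), censored times drawn
  uniformly below the event time.

What it does **not** emulate: batch structure, tumour subtype
heterogeneity, correlated miRNA families, realistic genomic coordinates,
isoform structure, or covariate-linked censoring. Passing tests
demonstrate that the procedures recover a planted architecture under
their own assumptions at realistic cohort sizes — not that real-cohort
results (which depend on interaction-database quality and much larger
feature spaces) are reproduced.

## Reference problem sizes

The automated checks run at: end-to-end recovery on cohorts of 200
tumour samples, 50 mRNAs, 30 miRNAs, 10 planted pairs (3 seeds,
n_perm = 500); stability-selection retention at n = 100 with 3 true
regulators (|β| = 0.5, σ = 0.2) among 20 decoys (5 seeds); permutation
null calibration with 500 replicates at n_perm = 200; Cox recovery of
log HR = 1 at n = 500. Observed: sensitivity 1.0 and FDR 0.0 end to
end, 100% true / ≤ 5% decoy retention, null rejection ≈ 0.04–0.06,
log-HR estimate within two standard errors of the target.

## Known limitations

- The DE stage approximates, not replicates, the edgeR/limma stack.
- The mscor permutation null differs from covariance-simulation nulls;
  adjusted p-values are comparable within a run, not across methods.
- The Cox fit is univariate by design (no clinical covariates).
- Candidate interactions are taken as given; no target prediction is
  performed.
- Cohorts are analysed as independent bundles; any sample-id
  harmonization (e.g. merging related cohorts) must happen upstream.
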