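# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions a user may need when comparing
against other implementations.

## The synthetic compendium

`simulate.generate_compendium` emulates a multi-experiment stress
compendium on the log2 scale and back-transforms to TPM:

    log2 TPM[g, s] = mu_g + DE effects + latents + shift_b + scale_b * eps[g, s]

* **Baseline** `mu_g ~ Normal(5, 2)` gives a heavy-tailed TPM dynamic
  range (median ~32 TPM, 95% inside ~0.25–4,000) without modelling counts;
  the pipeline consumes TPM, so noise is log-normal (`noise_cv`, the
  biological coefficient of variation; sd on the natural-log scale is
  `sqrt(ln(1 + cv^2))`), not negative binomial.
* **Design**: each stressor has `n_bioprojects_per_stressor` independent
  experiments (default 3, mirroring a typical "at least three independent
  experiments" inclusion rule), each with `samples_per_group` control and
  stressed samples. Default scale — 2,000 genes, 6 stressors × 3
  experiments × (6+6) samples = 216 samples — is the study condition used
  throughout the tests and the acceptance script.
* **Planted truth**: core genes gain (up) or lose (down)
  `log2(core_fold_change)` in the stressed group of *every* experiment;
  stress-specific genes only in their own stressor's experiments (all of
  them by default; `specific_bioproject_fraction` relaxes this to "at
  least one"). Defaults: 60 core-up, 40 core-down, 24 specific per
  stressor (half up, half down), fold change 4, CV 0.2.
* **Batch effects** are an additive per-experiment shift
  (`Normal(0, batch_shift_sd)`, default 1 log2 unit) plus a multiplicative
  scale on the noise (`exp(Normal(0, batch_scale_sd))`) — exactly the
  location/scale model ComBat assumes, so batch-correction tests are sharp
  rather than model-misspecification tests.
* **Regulatory and co-expression structure**: each TF has a latent
  per-sample activity (`tf_activity_sd`); its targets add
  `tf_regulation_strength` times that activity to their log profile.
  Co-expression blocks share a latent profile (`block_signal_sd`). Setting
  these sds to 0 together with zero noise/batch/effects yields a constant
  matrix (the degenerate sanity case).

What it does **not** emulate: read-level artifacts, isoform structure,
tissue- or genotype-specific programs (a two-tissue mode adds only a
global offset), correlated noise between genes outside blocks, and
realistic library-composition effects. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
performance on any real compendium, whose noise and batch magnitudes are
unknown.

## TN-ratio differential expression

`TN = (mean stressed TPM + 1)/(mean control TPM + 1)` per experiment, on
**raw** TPM: the ratio is within-experiment, so additive batch effects
cancel, and batch correction is reserved for the multivariate stages. The
+1 pseudocount keeps ratios finite and positive; thresholds are strict
(`> 2` up, `< 0.5` down; a ratio of exactly 2 is not called). Multiple
stress timepoints or levels within one experiment are pooled into one
stressed group. A gene up-called in one experiment and down-called in
another experiment of the same stressor joins both directional sets (the
union is per direction). The per-stressor union requires support from at
least one experiment; a stricter minimum is exposed as a parameter. The
pseudocount biases realized ratios of low-expressed genes toward 1, which
is why planted 4-fold genes show per-experiment TN-ratios centred slightly
below 4.

## Hold-one-stressor-out random forest

* **Split**: the test set is every sample (stressed *and* control) of the
  held-out stressor's experiments, so no information from that stressor —
  not even its control baselines — reaches training.
* **Class balance**: SMOTE interpolation between minority neighbours
  (k = 5, reduced with a warning when the minority class is smaller),
  applied after the split and inside each CV fold; validation folds and
  the test set are never resampled.
* **Tuning**: randomized search (budgeted, default 10 candidates) over
  bootstrapping, tree depth, feature sampling, leaf/split minima and tree
  count, scored by mean stratified-3-fold validation AUC. A full grid over
  six hyperparameters is not worth the compute at any scale we run.
* **Importances**: sklearn impurity-based importances (non-negative,
  sum 1). The final refit floors the tree count at
  `importance_trees = 500`: classification metrics converge with ~100
  trees, but importance *rankings* do not, and the core-gene intersection
  is a ranking statistic. This is the one place the model is deliberately
  larger than the tuned configuration.
* **Feature curve**: models are refit on top-X gene subsets
  (X = 50 … 15,000 by default); the "optimal" size is the smallest X with
  AUC within 0.01 of the best over sizes (the tolerance is our choice; no
  canonical value exists).
* **Core set**: intersection of the six per-model top-k sets; rank ties at
  the k boundary break by gene id. k = 6,000 is meaningful at ~40k genes;
  in synthetic tests k scales as 3× the planted-core count.

## Batch correction, PCA, dendrograms

ComBat is the standard parametric empirical-Bayes location/scale model
with batch as the only design variable (treatment labels are unbalanced
across batches and would not be identifiable). The implementation matches
`sva::ComBat` to ~1e-15 (cross-checked in the test suite). Genes constant
within every batch pass through unchanged; a single-batch input is
returned unchanged; a batch with one sample is an error naming the batch.
EB shrinkage has a visible consequence worth knowing: planted *variance*
ratios are re-centred on 1 but retain gene-level residual spread (at 50
samples/batch about 80% of genes land within [0.8, 1.25]); planted *mean*
shifts shrink by well over an order of magnitude.

PCA is centered but not scaled (features are already log-TPM on a common
scale); component signs are fixed by making each component's
largest-magnitude loading positive. Z-scores use the population sd
(divide by n, the sklearn convention) — fixed and relied on by tests.
Treatment dendrograms cluster per-treatment mean profiles of z-scored,
batch-corrected data (genes are z-scored across samples first, then
averaged per treatment) with Euclidean distance and average linkage; both
are configurable since no canonical choice exists.

## Co-expression networks

Unsigned adjacency `|cor|^power` (default power 9; unsigned is the
historical default and "signed" membership below is independent of it),
unsigned topological overlap, average-linkage clustering of the TOM
dissimilarity, and a static cut at height 0.9 with minimum module size 20.
A static cut is a deliberate simplification of dynamic tree cutting: with
soft-power-9 adjacencies, within-module TOM dissimilarities (~0.4 at
cor ≈ 0.95) and noise dissimilarities (~1.0) are well separated, so the
cut height is not delicate; it is configurable. Modules are labelled
M1… by decreasing size; unassigned genes form the background module M0.
No eigengene-merging step is applied.

Module eigengenes are the first right singular vector of the
gene-standardized module matrix, oriented to correlate positively with the
module mean profile; kME(gene, module) is the Pearson correlation of the
gene with the eigengene (signed membership in [−1, 1]). The hub threshold
is the 95th-percentile (type-7, linear-interpolation) quantile of assigned
genes' |own-module kME|; hubs exceed it strictly, so ~5% of assigned genes
are hubs up to ties.

## Enrichment

All overlap tests are one-sided (greater) Fisher exact tests — the p-value
is the upper hypergeometric tail — with the sample odds ratio
(ad)/(bc) (∞ when only the denominator is zero, NaN for 0/0). FDR is
Benjamini–Hochberg within one logical battery: all families for one gene
set, all terms for one set, all modules for one set; the pooled "all TFs"
test is corrected separately from the family battery. Classes: enriched
(q < 0.05), near (0.05 ≤ q < 0.1), ns. The default universe is every gene
in the analyzed matrix after zero-variance filtering; callers may
override. Term enrichment is the "classic" independent-per-term algorithm:
any ontology propagation must be done by the caller.

## Regulatory network and Dunnett comparisons

For each target gene a random-forest regressor (100 trees by default,
sqrt feature sampling) predicts its standardized expression from all TF
expressions (excluding itself if it is a TF); edge weights are impurity
importances and sum to 1 per target, making mean incoming weight
comparable across targets.

Group comparisons use classical pooled-variance Dunnett many-to-one tests
(scipy's multivariate-t implementation; the single-contrast case is
computed in closed form as the pooled t-test, which it equals exactly).
Because Dunnett on fixed data is deterministic, the repeated procedure
bootstrap-resamples targets within each group (with replacement, original
sizes) and re-tests — default 5,000 repetitions — rather than re-fitting
the network thousands of times, which would be computationally
disproportionate; network re-seeding is available as an alternative
repetition scheme at small scales. A comparison is significant when the
*upper* bound of the 2.5–97.5 percentile interval of its p-value
distribution is below 0.05 (the stricter of the two possible readings of
"the 95% interval is below 0.05"). Significance must be read together with
the sign of the group-mean difference, which the result table carries: a
group can be significantly *less* regulated than the control.

## Numerical conventions and degenerate inputs

* Zero-variance filtering tests `max − min > 0` (float-stable), not a
  variance threshold.
* TN-ratios require positive finite values; thresholds must satisfy
  down < up.
* A test set with one class yields accuracy/F1 but a missing AUC with a
  warning.
* Constant GRN targets get all-zero incoming weights with a warning.
* All stage seeds derive from one global seed via a stable hash of the
  stage name, so stages are independently reproducible; fixed seeds give
  bit-identical matrices, gene sets and edge lists.

## Problem sizes used in tests and the acceptance script

Recovery checks run at the default study conditions (2,000 genes, 216
samples); GRN recovery at 20 TFs × 10 targets each among 260 genes;
module recovery on two 30-gene blocks plus 100 noise genes; Fisher
exactness exhaustively over all 2×2 tables with total ≤ 60 against an
integer-arithmetic oracle; repeated-Dunnett calibration at 4 groups × 200
targets with 500 bootstrap repetitions per replicate. These sizes keep a
full run in the minutes range while leaving every statistic far from its
small-sample regime.

## Known limitations

* The static TOM cut is not dynamic tree cutting; very unequal module
  densities may need a different `cut_height`.
* SMOTE interpolates in full gene space; with few minority samples the
  synthetic points are nearly copies.
* The GRN stage fits one forest per gene and scales linearly in gene
  count; genome-scale runs should raise `n_jobs`.
* Recovery guarantees are with respect to the generator's model (shared
  log-normal noise, ComBat-form batches); real compendia violate it in
  unknown ways.
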