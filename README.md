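# corestress

Core and stress-specific abiotic-stress gene discovery from
multi-experiment expression compendia.

Plants meet drought, heat, cold, salt, flooding and nutrient starvation
with partly shared transcriptional programs. Given a compendium of RNA-seq
experiments — a genes × samples TPM matrix plus per-sample metadata
(experiment/BioProject, treatment, tissue, genotype) — `corestress`
identifies the **core stress-responsive genes** (responsive under *every*
stressor) and the **stress-specific genes** (responsive under exactly one),
then characterizes them with co-expression modules, enrichment statistics
and regulatory-network comparisons. It is aimed at plant-transcriptomics
groups running meta-analyses over heterogeneous public data, where each
experiment is its own batch.

## Methods at a glance

**TN-ratio differential expression.** Within each experiment *e* and gene
*g*, on raw TPM:

    TN_e(g) = (mean stressed TPM + 1) / (mean control TPM + 1)

with calls *up* if TN > 2 and *down* if TN < 0.5 (strict). Per stressor
*s*, `up(s)` is the union of up-calls over that stressor's experiments;
core sets are intersections across stressors, `core_up = ∩_s up(s)`;
a gene is *s*-specific iff it is called under *s* and under no other
stressor.

**Hold-one-stressor-out random forest.** Six binary stress/control
classifiers on batch-corrected log₂(TPM+1); for each, *all* samples of one
stressor's experiments are held out as the test set, training folds are
SMOTE-balanced, hyperparameters are tuned by randomized search with
stratified CV on the training set only. The intersection of the six top-*k*
feature-importance sets (k = 6,000 at genome scale) is the random-forest
core set; the combined core set is the union of both methods.

**Supporting stages.** Parametric empirical-Bayes batch correction
(ComBat, verified against `sva::ComBat` to machine precision), centered
PCA, treatment dendrograms; weighted co-expression networks
(|cor|⁹ adjacency, topological-overlap modules, module eigengenes,
signed kME, hubs above the 95th percentile of |kME|); one-sided Fisher
enrichment with Benjamini–Hochberg FDR for TF families and gene→term maps;
GENIE3-style random-forest regulatory-network inference with
bootstrap-repeated Dunnett comparison of mean regulatory weights across
gene classes.

A synthetic-compendium generator (`corestress.simulate`) plants core genes,
stress-specific genes, co-expressed blocks, TF→target structure and
per-experiment batch effects with known ground truth, so every stage is
testable without downloading data.

## Worked example

```bash
corestress simulate --out sim --seed 1
corestress preprocess --expr sim/expression.tsv --meta sim/metadata.tsv --out corrected.tsv
corestress de --expr sim/expression.tsv --meta sim/metadata.tsv --out de_out
```

prints

```
wrote compendium (2000 genes x 216 samples) to sim
wrote 2000 genes x 216 samples to corrected.tsv
core: 60 up, 40 down
```

i.e. the simulated compendium (6 stressors × 3 experiments × 12 samples)
is batch-corrected, and the TN-ratio set operations recover exactly the
60 planted core-up and 40 core-down genes (`de_out/core_up.txt`,
`core_down.txt`, plus `specific_<stressor>_<dir>.txt` per stressor).
The same analysis runs from Python:

```python
from corestress import SimConfig, generate_compendium, run_tn_ratio_analysis, score_recovery

expr, meta, truth = generate_compendium(SimConfig(seed=1))
sets = run_tn_ratio_analysis(expr, meta)
print(score_recovery(sets.core, truth.core, set(expr.index)))
# RecoveryMetrics(precision=1.0, recall=1.0, f1=1.0)
```

The full pipeline (preprocess → DE → RF → co-expression → enrichment →
GRN, with provenance JSON per stage) runs from one YAML config:
`corestress run --config pipeline.yaml`.

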