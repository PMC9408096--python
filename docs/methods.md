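# Methods

## Problem and model

`synloc` predicts whether a brain-expressed RNA is dendritically
(synaptically) localized or retained in the neuronal soma.  This is cast
as binary classification: positives are dendritically localized RNAs,
negatives somatic RNAs, both compiled from multiple independent profiling
studies, and two feature families describe each gene:

* **Sequence features** — overlapping k-mer frequencies (k = 1, 2, 3 by
  default; 4 + 16 + 64 = 84 features) of the concatenated 5′ + 3′ UTR of
  the gene's representative transcript (the one with the longest coding
  sequence).  Counts are divided by the concatenated length L, so for an
  N-free sequence the 4^k frequencies of one k sum to (L − k + 1)/L, not
  1.  Windows containing an ambiguous base N are skipped; the denominator
  stays L.  The 5′ UTR precedes the 3′ UTR in concatenation — immaterial
  for frequency features, but fixed for reproducibility.
* **Expression features** — one feature per sample of a developmental
  brain expression matrix (genes × samples in RPKM, each sample annotated
  with an age stage and a brain structure), transformed as
  log2(RPKM + 1).

Both families are min–max scaled per feature.  The scaler is always
fitted on training data only (training folds inside cross-validation)
and applied to held-out data with clipping to [0, 1]; a constant feature
maps to 0.  Fitting the scaler per split avoids information leaking from
test folds into the transform.

## Training-instance compilation

1. Each study's gene list is mapped to human gene IDs through a
   many-to-many ortholog table (unmapped genes are dropped and counted).
   One-to-many expansion happens *before* overlap counting, so a human
   gene supported by two studies via different source genes counts as
   two studies.
2. Genes reported by at least `min_studies` (default 2) independent
   studies of the same label are kept.
3. Candidate negatives that overlap the positive set are removed
   (exclusion happens in human ID space, after mapping).
4. Genes must show expression support: RPKM strictly greater than 1.0 in
   at least ceil(0.01 × n_samples) samples (minimum one sample).

Gene identifiers are opaque strings; a trailing `.N` version suffix is
stripped on ingest because cross-source set intersection requires exact
ID equality.

## Classifier families

Five families share one train/predict contract (probabilities in [0, 1],
columns aligned by name, seeded determinism):

| family | backing estimator | imbalance handling |
|---|---|---|
| `logreg` | penalized logistic regression | inverse-frequency class weights |
| `maxmargin` | RBF-kernel max-margin classifier, sigmoid-calibrated on internal held-out folds | class weights |
| `random_forest` | random forest (impurity splits) | class weights |
| `gradient_boosted_trees` | gradient-boosted trees (xgboost), `scale_pos_weight` | positive-class weight |
| `ann1` | one-hidden-layer multilayer perceptron | bootstrap balancing |

The `ann1` network uses an L2 penalty (`alpha`) as its capacity control;
its training data are bootstrap-balanced — the minority class is
resampled with replacement up to the majority size — instead of
class-weighted, and this resampling happens inside each training fold
during cross-validation.  With already-balanced input the positive class
is still re-drawn, keeping counts unchanged.  Max-margin probabilities
come from a sigmoid calibration of decision scores on internal
stratified folds, which keeps the probability threshold of 0.5
meaningful for a margin classifier.

Hyperparameter grids live in configuration, not code; `grid_search`
maximizes mean CV ROC-AUC with ties broken by first-in-grid order.

## Evaluation

Five repetitions of stratified 10-fold cross-validation.  Threshold
metrics (threshold 0.5, with probability **≥** 0.5 predicting positive)
are accuracy, sensitivity, specificity, F1 and MCC computed from the
confusion table; zero-denominator ratios return 0 with a degenerate flag
rather than NaN so pooled means stay defined.  ROC-AUC is the
tie-corrected Mann–Whitney rank statistic; PR-AUC is the step-wise
(average-precision) estimator, avoiding the optimistic bias of linear
interpolation in PR space.  Pooled CV numbers are means over all
repetition × fold fold-level metrics (not pooled predictions), matching
how per-fold importance scores are averaged.  Independent-test
evaluation verifies train/test instance disjointness and errors on
overlap; on a single-class test set the threshold metrics are computed
and the AUCs are undefined (`None` + flag).

## Feature selection

A random forest is fitted on each of the 50 CV training folds; mean
impurity-decrease importance over all fits ranks features (each single
fit's importances sum to 1).  Permutation importance is available as an
option.  For expression features (named by sample), importances are
averaged per (age stage, tissue) cell, excluding features with exactly
zero mean importance, and the grid's rows/columns are sorted by
descending marginal importance — the same view used to ask which
developmental windows and brain structures carry the signal.  Cells
weight each sample equally regardless of how many samples share the
cell.

## Consensus prediction and enrichment

Three trained models score every gene; genes with all three
probabilities ≥ 0.5 form the high-confidence consensus list (so the
consensus count is bounded by the smallest single-model positive count),
and genes are ranked by the arithmetic mean of the three probabilities
(ties broken by gene ID for determinism).

Enrichment of a reference gene set in that ranking uses a weighted
KS-style running sum: walking down the list, hits add
|score|^p / Σ_set |score|^p (p = 1 by default, the standard weighted
setting) and misses subtract 1/(N − n_set).  The running sum starts at 0
and ends at 0; the enrichment score is its signed maximum-magnitude
deviation, and the leading edge is the set members at or before (after,
for negative ES) the peak.  The null distribution draws random gene sets
of the same size from the ranked list — the standard preranked surrogate
for phenotype permutation — and the nominal p-value is the fraction of
same-sign permutation scores at least as extreme, with the plus-one
correction so p ≥ 1/(n_permutations + 1) and is never exactly zero.

## Synthetic data generator

The generator emulates every input so the pipeline is testable without
downloads.  Defaults are the package's study conditions: 300 positive
and 300 negative genes; a 5-tissue × 8-age-stage × 5-sample expression
grid (200 features); 20 signal features; effect size 2.0 log2 units;
noise SD 1.0; baseline log2 expression 2.0; UTR lengths 100–500 nt.

* **Expression** — per-cell log2 values are Gaussian; RPKM = 2^x − 1
  clipped at 0 (log-normal marginals, so the RPKM > 1 filter acts
  non-trivially at low baselines).  Positive-class genes are shifted by
  the effect size on a contiguous block of early (age, tissue) sample
  columns, so the importance-grid aggregation can be checked against
  planted ground truth.  With effect size 0 the classes are
  exchangeable.
* **UTRs** — i.i.d. uniform nucleotides; an optional k-mer bias
  multiplicatively enriches chosen words in positive-class sequences via
  a biased emission process (insert word m with probability
  (factor − 1)·4^−k per position).
* **Study lists** — each gene lands in two studies of its label with a
  configurable probability (else one), through per-study rodent-style
  source IDs and an ortholog map; a few positive genes are planted into
  negative studies to exercise the exclusion rule, and orphan source IDs
  exercise unmapped-gene handling.  The generator's bookkeeping (not a
  re-run of the overlap logic) records which genes are supported by ≥ 2
  studies, so the dataset builder can be checked for exact agreement.

What the simulation does **not** model: real covariance between brain
samples, developmental trajectories, sequence composition biases of real
UTRs, or many-to-one ortholog ambiguity beyond the planted cases.
Passing recovery tests therefore shows the machinery is correct and
calibrated, not that comparable accuracy is attainable on real data.

## Numerical and design choices

* "At least 1% of samples" uses ceil(0.01 × n_samples) with a minimum of
  one sample; RPKM comparison is strict (`>`).
* Feature-selection ties break lexicographically; ranking ties break by
  gene ID; grid-search ties break first-in-grid.
* The per-stage seeds of the CLI derive from one global seed by hashing
  the stage name (values < 2^31), so stages re-run in isolation
  reproducibly; every CLI run writes a JSON manifest with the seed,
  parameter hash and input checksums.
* Problem sizes in the test-suite recovery experiments use the
  generator's default study conditions (600 genes × 200 features); null
  calibrations use single-repetition 10-fold CV with the logistic
  family, which is statistically equivalent for a chance-level check and
  keeps the experiments light.

## Known limitations

* The bundled conditions are synthetic; no claims are made about
  reproducing published accuracy on real rodent-derived instances.
* `ann1` is a dense single-hidden-layer network without dropout;
  regularization is via L2 weight decay.
* Enrichment is computed per gene set without multiplicity correction
  (the intended use is a single curated synaptic set).
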