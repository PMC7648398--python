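# lncprior

Machine-learning prediction and prioritization of disease-associated long
non-coding RNAs (lncRNAs), transferring knowledge from protein-coding risk
genes. The package implements the full workflow for autism spectrum disorder
(ASD) risk-gene modelling: known protein-coding risk genes (SFARI categories
S/1/2/3) are the positive class, curated non-ASD disease genes the negative
class, and the trained models score unlabeled lncRNAs as candidates.

## The model

Every gene is represented by two feature blocks:

* **Expression codes.** Developmental brain expression profiles (BrainSpan-style
  RPKM over 524 samples in real mode) are transformed as `log2(RPKM + 1)` and
  compressed with a single-hidden-layer autoencoder,
  `x_code = ReLU(W_enc x_in + b_enc)`, `x̂_in = ReLU(W_dec x_code + b_dec)`,
  trained with MSE loss and the RMSprop optimizer (100 epochs, batch size 64).
  The code dimension is chosen by grid search on cross-validated ROC AUC
  (48 on the real data shape).
* **Selected k-mers.** Each transcript's 3-/4-mer frequencies (4³ + 4⁴ = 320
  features, each count normalized by the sequence length *L*) are ranked by
  random-forest impurity importance averaged over 10 differently seeded fits,
  and the top *m* retained (grid 10–50, 25 on the real data shape).

The concatenated features are min–max scaled and fed to three class-weighted
binary classifiers — logistic regression, an RBF-kernel SVM with Platt-style
probability calibration, and a random forest — with the negative:positive
weight ratio 1 : n_neg/n_pos (1 : 2.6391 for 604/1,594 training genes).

Evaluation is repeated stratified tenfold cross-validation with accuracy,
sensitivity, specificity, precision, Matthews correlation coefficient (at the
0.5 probability threshold), ROC AUC (trapezoidal) and PR AUC (step-wise; the
random baseline is the positive prevalence). Two further analyses probe the
models:

* **Hypothetical-locus validation.** For each known risk gene, the *N* genes
  centered on it along its chromosome (N = 101, 201, 401 presets) form a
  locus; the model is retrained without the target, every member is scored,
  and the target's percentile rank is `L / N × 100` with *L* the number of
  members scoring strictly below it. A random ranker averages ≈ 50; a useful
  model pushes known risk genes toward 100.
* **Candidate prioritization.** Unlabeled lncRNAs are scored by all three
  models; calls at the 0.5 threshold, the three-model consensus, co-expressed
  protein-coding partners (Pearson correlation > 0.95 on log2 expression) and
  genomic overlap with risk genes (same locus / antisense) are reported.

Because the real inputs are large external downloads, the package ships a
fully parameterized synthetic-data generator that emulates all four inputs at
reduced scale (150/396/100 genes, 60 samples, five 4-mers planted at 5×
enrichment, antisense lncRNA/risk-gene pairs) with the same 1:2.64 class
imbalance, so the complete pipeline is testable end to end on a laptop.

## Worked example

```bash
lncprior run --demo --seed 0 --out demo_run
```

runs the whole pipeline on the strong-signal synthetic preset (646 genes ×
60 samples; 16 expression codes + top-25 k-mers) in well under a minute and
prints `run complete; manifest hash 576d21e836210fc4`. The run directory then
contains, among others:

* `cv_report.json` — repeated tenfold CV: all three models reach
  ROC AUC 1.0000 on this preset (the planted expression shift of 2.0 log2
  units across 20 samples is easily separable; on null data with no planted
  signal the same pipeline stays at ROC AUC ≈ 0.5).
* `loci_summary.tsv` — mean hypothetical-locus percentile rank 85.85
  (N = 51, 40 targets): known risk genes are ranked near the top of their
  loci even though each was excluded from its own training set.
* `manifest.json` — `"selected_kmers"` starts
  `CACA, AATT, GGCC, CGCG, TATA, ...`: the five planted 4-mers lead the
  importance ranking, followed by their substring 3-mers; class weights are
  reported as `[1.0, 2.64]` (396/150).
* `candidates.tsv` — of 100 unlabeled lncRNAs, exactly the 10 that carry the
  planted positive signal are called by all three models, and the 10 planted
  antisense lncRNAs are annotated `antisense`.

Every stage is also available as a subcommand (`simulate`, `encode`, `kmers`,
`select-kmers`, `train`, `evaluate`, `validate-loci`, `prioritize`) operating
on plain TSV/FASTA/JSON files; rerunning any stage with the same seed
reproduces its outputs byte for byte.

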