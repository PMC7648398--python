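# Methods

This note records the modelling choices, defaults and numerical details of
the lncprior pipeline, and what its synthetic benchmark does and does not
show about real data.

## Problem setting

The pipeline is a transfer-learning formulation of lncRNA–disease
association: all confidently known ASD risk genes code for proteins, so a
binary classifier is trained on protein-coding genes (known risk genes vs
curated non-risk disease genes) using only features that are equally defined
for lncRNAs — expression profiles across developing brain samples and
transcript sequence composition — and then applied to unlabeled lncRNAs.
The key assumption is that risk genes share developmental-expression and
sequence signatures that transcend coding status.

## Expression block

1. `log2(RPKM + 1)` transform of the raw matrix. Strictly monotone; exact
   inverse `2^y − 1`.
2. A single-hidden-layer autoencoder (encoder `input_dim → code_dim`,
   decoder `code_dim → input_dim`, ReLU on both layers) trained on the log2
   matrix with MSE loss and RMSprop (decay 0.9, epsilon 1e-8), 100 epochs,
   batch size 64, learning rate 1e-3. The learning rate is not dictated by
   the protocol we follow; 1e-3 is the conventional RMSprop default and is
   exposed in `AutoencoderSpec`. No early stopping and no validation split:
   the epoch count is fixed.
3. Min–max scaling is applied to the *combined* feature set (codes +
   selected k-mers) at classification time, not to the autoencoder input;
   the autoencoder consumes the log2 matrix directly. Both orders are
   supported, this one is the default.

Numerical details that matter:

* **Initialization.** Encoder weights uniform on ±1/√fan_in; decoder weights
  uniform on [0, 1/√fan_in]; biases zero; all drawn from the spec seed. The
  non-negative decoder start is deliberate: with a ReLU output layer
  reconstructing non-negative data, an output unit whose pre-activation is
  negative for every training example receives zero gradient and can never
  recover, and a symmetric decoder initialization strands roughly half the
  output dimensions this way (reconstruction MSE then exceeds the input
  variance). With the non-negative start, rank-k data with `code_dim = k`
  is reconstructed to ~2% of the input variance in 100 epochs.
* **Determinism.** One generator (from the spec seed) drives initialization
  and every epoch's mini-batch shuffle, so loss traces and weights are
  bit-reproducible.
* **Transductive caveat.** The autoencoder is fit once on all genes, labeled
  and unlabeled together, and not refit per CV fold. This mirrors the
  workflow it implements (a single encoding chosen before CV; unlabeled
  lncRNAs must be encodable in the same space). It is label-free, so it
  cannot leak class information, but it does see the held-out genes'
  expression values.
* The code dimension is chosen by grid search on repeated-CV mean ROC AUC
  of a classifier on the encoded features; ties go to the smaller size.

## Sequence block

* k-mer frequencies: overlapping count of each 3- and 4-mer divided by the
  full sequence length *L* (not the window count `L − k + 1`; the two
  conventions differ and the length convention is used throughout, so the
  per-k frequencies of an N-free sequence sum to `(L − k + 1)/L` exactly).
  Windows containing N are dropped from numerators while *L* keeps its full
  value — conservative and deterministic. The feature space for k ∈ {3,4}
  is 4³ + 4⁴ = 320 columns.
* Ranking: the class-weighted random-forest classifier is fit 10 times with
  distinct sub-seeds on the min–max-scaled frequencies; impurity importances
  (each fit's importances sum to 1) are averaged and sorted descending with
  lexicographic tie-breaks. Columns are put in canonical (k, name) order
  before fitting because the forest's per-node feature draws depend on
  column position; this makes the ranking invariant to the caller's column
  permutation. Permutation importance is available via
  `model_config.hyperparameters` if wanted, but impurity importance is the
  default, matching the ensemble implementation's convention.
* Selection: the top-m column subsets over the grid (default 10..50 step 5)
  are compared by repeated-CV mean ROC AUC; ties to smaller m. The same RF
  configuration is shared between ranking and classification.
* The Welch two-sample t-test report (unequal variances,
  Welch–Satterthwaite df, two-sided, no multiplicity correction) screens
  selected k-mers for class-differential frequency; a k-mer with zero
  variance in both classes is reported t=0, p=1 and flagged.

## Classifiers

LR (lbfgs, implicit L2, C=1), SVM (RBF, C=1, gamma='scale', Platt-style
sigmoid calibration fitted by internal cross-validation on the training
folds), RF (500 trees). The tuned hyperparameter values used in the original
study are not public, so these are conventional defaults, all overridable
per model. Class weights are `w_neg = 1`, `w_pos = n_neg/n_pos` (2.6391 at
the real 604/1,594 class sizes), computed from the training labels at fit
time; at a 1:1 ratio the weighting is a no-op. Min–max statistics are fit on
the training rows only and stored with the model, so CV folds and candidate
genes are always scaled with training statistics; a `global_stats` argument
reproduces the scale-once-globally variant.

## Evaluation

* Stratified folds: each class shuffled independently and dealt round-robin,
  so per-class fold sizes differ by ≤ 1 and every fold preserves the global
  imbalance (604/1,594 at k=10 gives 60–61 positives and 159–160 negatives
  per fold).
* Count metrics (accuracy, sensitivity, specificity, precision, MCC) use
  the fixed 0.5 probability threshold — the same threshold the
  prioritization stage uses for calling candidates. Zero-denominator
  metrics are NaN and flagged (MCC → 0, flagged); fold averages skip NaNs.
* ROC AUC: trapezoidal over unique-score thresholds; identical to the
  Mann–Whitney probability with ties counted ½ (tested to 1e-12).
* PR AUC: step-wise right-continuous precision rule. For constant scores it
  equals the prevalence; accordingly the random-guess PR baseline reported
  alongside is the prevalence (≈ 0.275 at the real class sizes), not 0.5.
* Aggregation: mean over the k folds per repetition, then mean ± sd across
  repetitions.

## Hypothetical-locus validation

Loci are built from start-coordinate order on the target's chromosome,
strand-agnostic; (N−1)/2 genes on each side, extending on the long side near
chromosome ends and truncating to the chromosome when it holds fewer than N
genes (`N_actual` records the achieved size — the original protocol does not
say how chromosome ends were handled; this extension rule is this package's
choice, as is coordinate order over annotation-file line order). Only the
target is removed from training; labeled genes inside the locus are scored
like any candidate. Ties with the target's probability do not count toward
L (strict less-than), so clustered high-scoring positives depress each
other's percentile — visible in synthetic layouts that intersperse
positives. The LR model is the leave-one-out default (one retrain per
target); RF/SVM are available per config.

## Prioritization

Candidates are ranked by the mean of the three model probabilities (the
composite ordering is not dictated by the protocol; mean is the default,
with ties broken by gene id). Calls use a 0.5 threshold per model;
`consensus_all` requires all three. Co-expression partners are
protein-coding genes with Pearson correlation > 0.95 against the candidate
on the log2 matrix; zero-variance vectors are skipped with a flag. Genomic
overlap is interval intersection (1-based inclusive coordinates, ≥ 1 shared
base, same chromosome); an opposite-strand intersecting risk gene makes the
candidate `antisense`, otherwise `same_locus`.

## Synthetic benchmark

The generator emulates the four real inputs at a reduced scale chosen so
the full pipeline runs in minutes on one CPU:

| parameter | default | rationale |
|---|---|---|
| n_pos / n_neg | 150 / 396 | preserves the real 1:2.64 imbalance |
| n_unlabeled | 100 (10 carrying the full positive signal) | candidate pool with known ground truth |
| n_samples / n_signal_samples | 60 / 20 | a third of columns informative |
| mu_base, expr_effect, expr_noise_sd | 3.0, 2.0, 0.5 (log2 units) | strong but not degenerate expression signal |
| informative k-mers | CGCG, TATA, GGCC, AATT, CACA at 5× | 4-mers chosen a priori: the same planted count on a 4× smaller background than 3-mers gives a larger per-gene effect |
| seq_len_range | 500–3000 nt | lncRNA-like transcript lengths |
| genes_per_chromosome / antisense_fraction | 50 / 0.1 | loci constructible; 10 planted antisense pairs |

Expression is Gaussian on the log2 scale per class (mapped back to RPKM via
`2^x − 1`, clipped at 0); sequences are i.i.d. uniform with planted k-mers
inserted at uniformly random positions (overwriting bases, preserving
length, a Poisson number of insertions matching the excess over the uniform
background rate); the annotation shuffles genes into fixed-size chromosomes
with non-overlapping intervals except the planted antisense lncRNAs, each
strictly inside a distinct positive gene's interval on the opposite strand.
One global seed spawns independent sub-streams per artifact, so each file is
reproducible in isolation. A `realistic_scale()` preset restores the
604/1,594/524 shape.

What passing tests on this benchmark show: the pipeline recovers planted
signal of realistic geometry (distributed across many samples and k-mers),
respects its determinism and stratification contracts, and stays at chance
on null data. What they do not show: performance on real developmental
trajectories (BrainSpan's samples are structured by age and region, not
i.i.d.), on realistic sequence composition (real transcripts are not
uniform-random, and k-mer frequencies are strongly correlated), or at the
real feature-to-sample ratio; the published headline AUCs cannot be
reproduced without the external data.

One measurement subtlety the null benchmark exposed: ranking k-mers on all
labeled data and then cross-validating on those same labels is itself a
supervised step, and on pure-noise data it alone lifts apparent CV ROC AUC
to ~0.68. The null-calibration check therefore evaluates the
label-independent feature set (autoencoder codes + all 320 k-mer columns),
which stays within 0.05 of 0.5. Users applying the pipeline to real data
should note the same caveat when interpreting CV results obtained after
whole-dataset feature selection.

## Scaled-down analysis sizes

Tests and the demo run the protocols at reduced sizes chosen as sensible
desk-scale defaults: CV with 2–5 repetitions (the full protocol uses 50),
locus validation at N = 51 on up to 150 targets, importance ranking with the
full 10 repetitions. All counts are configuration, not code.

## Known limitations

* The autoencoder is plain (no denoising/variational variants, single
  hidden layer) by design; deeper variants are out of scope.
* SVM probability calibration quality at desk-scale sample sizes is rough;
  consensus calls mitigate but do not remove this.
* The leave-one-out validator retrains one model per target; RF at
  realistic scale is expensive (LR is the default for this stage).
* Reverse-complement k-mer collapsing, gapped k-mers and position-specific
  motifs are not implemented.
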