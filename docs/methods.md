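# Methods

## Overview

`tilescope` implements an integrative histopathology analysis: weakly
supervised tile-level classification of H&E slides with patient-level vote
aggregation, lymphocyte-centric interpretation of the trained classifiers
(first-layer filter colocalization, filter ablation, morphometric
infiltration scoring), and a parallel expression-based classifier with
gene-set over-representation. Because the cohorts such analyses are run on
(multi-gigapixel whole-slide images with clinical receptor-status labels)
are large and access-restricted, the package ships a synthetic
slide/expression generator with pixel-exact ground truth, and every claim
the test suite makes is a parameter-recovery or calibration statement on
that generator.

## Tile extraction and cohort splitting

A tile's **density** is the fraction of its pixels that are non-white,
where a pixel is non-white only when all three RGB channels are strictly
below 200. Candidate windows are enumerated on a regular grid
(default 224 px windows, non-overlapping stride 224; windows that do not
fit entirely inside the slide are discarded), and the top k = 200 windows
by density are kept, ties broken by row-major origin order so selection is
deterministic. Slides scanned at 40x are block-mean downsampled 2x before
tiling so a tile covers comparable tissue area at either magnification.

Cohort splits operate on **tissue source sites**, never on patients or
tiles: sites are visited in seeded random order and each is assigned to
the partition with the largest remaining patient-count deficit relative to
its target fraction. This greedy site-level scheme keeps realized patient
fractions within a few points of the targets (verified over seeds) while
guaranteeing that no site — and hence no staining/scanning batch — spans
two partitions.

## Tile classifier

Tiles inherit their slide's label (weak supervision). The default
`small_cnn` is a compact CNN implemented in numpy (three conv blocks:
8 filters of 5x5, then 16 and 32 of 3x3, max-pooling between, global
average pooling, dropout, softmax head) trained with Adam, class-weighted
cross-entropy, decoupled weight decay and random
rotation/shift/zoom/reflection augmentation. All randomness (init,
shuffling, dropout, augmentation) derives from one seed and execution is
single-threaded numpy, so runs are bit-reproducible on CPU. Architectures
are pluggable through a registry; heavier backbones can be registered by
the user without touching the training, aggregation or interpretability
code, which only assume a first convolutional layer and a probability
output.

Numerical choices that mattered:

- **Input representation.** Tiles are block-mean downscaled (default 4x,
  so a 224 px tile enters as 56x56) and intensity-complemented to *stain
  darkness* (1 − value/255). On raw intensities the sparse dark-nucleus
  signal rides on a ~0.9 white background mean and SGD at usable learning
  rates collapses to the constant classifier; on the darkness scale the
  background is ~0 and convergence is fast.
- **Defaults.** lr 2e-3, dropout 0.2, weight decay 1e-4, 6 epochs,
  batch 32. Dropout stronger than 0.2 materially slows convergence of
  this small model; the values were chosen on the separable toy task and
  the default synthetic cohort and are exposed in `TrainConfig`.
- **Augmentation fill.** Borders exposed by rotation/shift are filled
  with slide white (255 on raw tiles, 0 on the darkness scale).

**Fine-tuning to an external cohort** selects a fraction (default 10%) of
external *patients* — not tiles — mixes their tiles with the primary
training tiles, and continues training at a 10x reduced learning rate.
The operation returns the list of external patients excluded from
fine-tuning; evaluation is only valid on those.

## Aggregation and metrics

**Range voting** averages tile probabilities per class within a patient;
**first-past-the-post** lets each tile vote for its argmax (ties to the
lowest class index) and reports vote fractions. AUC is computed as
Mann–Whitney concordance P(s⁺ > s⁻) + ½P(tie) at the patient level, with
the aggregated positive-class probability as the score. Top-k accuracy
counts a patient correct when the true label ranks among the k highest
probabilities, ties broken by fixed class order. Confidence intervals are
nonparametric patient-level bootstrap percentile intervals
(default n_boot = 2000); resamples missing a class are redrawn. Coverage
of the 95% interval at true AUC 0.8, n = 100 patients is 90–99% over
replicate draws (checked in the suite).

## Lymphocyte quantification

Nuclei are segmented by thresholding stain darkness (complement of the
green channel — the channel in which both hematoxylin-dark lymphocytes
and paler tumor nuclei separate best from stroma) at max(Otsu, the
non-white floor of 200), filling holes, watershed-splitting touching
objects on the distance transform, and discarding objects under 15 px².
Each object gets area, perimeter, eccentricity, solidity, circularity
(4πA/P², clipped to 1) and per-channel intensity mean/sd. A random forest
(200 trees) over this feature vector calls lymphocyte vs other; accuracy
is reported as balanced accuracy on a stratified held-out object split.
The patient **infiltration score** is the unweighted mean over the
patient's tiles of the per-tile lymphocyte/cell fraction; tiles with no
detected cells are excluded from the mean (a score is undefined, and
refused, when every tile is cell-free).

## Filter interpretability

Only the first convolutional layer retains near-pixel resolution, so
interpretation stops there. Per filter and tile, the post-ReLU activation
map is binarized — default: top decile of |activation|, with Otsu as the
alternative; when ≥90% of the map ties at the minimum (a sparse detector)
only strictly supra-threshold cells are kept, and a constant map yields
an empty, flagged mask — then nearest-neighbor upsampled to tile
resolution and Pearson-correlated with the lymphocyte-only mask and with
the all-nuclei mask. A filter is **preferentially lymphocyte-colocalized**
on a tile when |r_lymph| > |r_nuclei| (magnitude comparison by default,
signed optional); the fraction of usable tiles where this holds ranks the
filters. Both per-tile-averaged and pooled (all pixels concatenated)
correlations are reported, since either convention is defensible.
**Ablation** zeroes one filter's kernel and bias, leaves every other
weight untouched, and re-measures patient-level (range-voted argmax)
accuracy.

### The planted-filter experiment

The causal claim — the filter that colocalizes with lymphocytes carries
the class signal — is tested mechanistically. In fully trained
`small_cnn` models at this scale the importance of any single first-layer
filter is diffuse (several redundant dark-spot detectors emerge, and
ablating one rarely moves patient accuracy), so the experiment instead
uses a shallow registered architecture (conv → ReLU → global average
pool → linear head) in which each head feature is exactly one filter's
mean activation. One filter is hand-planted as a thresholded dark-disc
detector (mean 3x3-center darkness, firing only above 0.5 — lymphocyte
cores are ~0.7 dark, tumor nuclei ~0.3), the remaining filters keep their
random initialization, and the head is fitted as a logistic readout on
the pooled features. Colocalization then *discovers* the planted filter
as top-preferential, and ablating it removes essentially all class
signal, while ablating the median-ranked filter does nothing — the
comparison the suite asserts over 10 replicate cohorts.

## Expression models

Expression classifiers are ridge-penalized linear models
(`RidgeClassifierCV`, penalty grid 1e-2…1e4 chosen by internal
cross-validation) on z-scored genes, with the receptor genes themselves
(ESR1/PGR by default) dropped *before* fitting so predictive signal must
come from correlated programs. Held-out AUC is computed on a stratified
25% sample split untouched by fitting. `log2(x+1)` preprocessing is
available for count-scale input; the synthetic generator already emits
z-scale values, so it defaults off. Single-gene baselines use one gene's
raw expression as the score, oriented so AUC ≥ 0.5. Gene-set
over-representation is one-sided hypergeometric per set (sets intersected
with the universe), BH-adjusted across sets; the **immune fraction** is
the share of significant sets (adjusted p < 0.05) carrying a caller-
supplied immune tag. The "top-ranked genes" queried default to the top
100 by |standardized coefficient| (the count is unspecified in this kind
of analysis; 100 is configurable).

## Two-sample statistics

The KS test uses the exact two-sample null distribution when
n_a·n_b ≤ 100 and the asymptotic one otherwise. The **bootstrap Δmean
test** resamples each group independently with replacement (default
n_boot = 1e5) and reports the two-sided sign-crossing p-value
2·min(frac(Δ* ≤ 0), frac(Δ* ≥ 0)) clamped to [1/n_boot, 1]; when no
resample crosses zero the p-value is printed as "< 1/n_boot". A
permutation test is available behind `permutation_mean_diff` as the
alternative construction. Null calibration at α = 0.05 is 3–7% over 1000
replicates (asserted in the suite). In the grouped comparison table,
ordinal scores with ≤ 5 distinct levels (e.g. pathologic stage) are
refused by the KS test and reported "n/a"; the bootstrap test still runs.
Concordance accounting cross-tabulates paired ER/PR labels, reports the
concordant fraction and the mean classifier confidence (aggregated
probability of the predicted class) per (status, concordance) cell, and
compares concordant vs discordant confidences with a KS test per status
column, flagging degenerate columns.

## Synthetic data

Slides are rendered as an elliptical pale-pink tissue section on white
glass (both ≥ 200 in every channel, so only nuclei count toward tile
density). Tumor nuclei are pale-stained ellipses with 8–16 px radii;
lymphocytes are dark basophilic discs with 3–6 px radii, drawn last so
masks stay pixel-exact under overlap. Cells are placed as a homogeneous
Poisson process over the tissue (default 35 per tile area). Each
patient's lymphocyte fraction is drawn from a Beta distribution centred
on its class rate (concentration 50), giving overlapping within-class
distributions; the defaults plant rates 0.05 (receptor-positive-like
class) vs 0.30, with higher infiltration in the "negative" class — the
direction is configurable. Class-conditional infiltration is the *only*
class signal in the images, so classifier ablation experiments have a
known causal pathway. Expression matrices plant the receptor gene as a
clean standardized shift (single-gene AUC Φ(δ/√2) in closed form) and an
immune program of genes sharing both the class shift and a latent
per-sample factor (pairwise r ≈ 0.25); all other genes are noise.

What the generator does *not* emulate: stain variation and deconvolution,
pyramidal multi-resolution structure, tissue texture (stroma is flat
noise), nucleus chromatin structure, touching-cell clumps beyond random
overlap, FFPE-vs-frozen artifacts, and batch effects between sites.
Passing tests therefore demonstrate that the pipeline's machinery
recovers planted signals under its own model assumptions — not that a
small CNN trained here would transfer to real slides.

## Problem sizes

The suite and the reproduction script run the image pipeline at 40
patients x 50 tiles (1792x1568 px slides) for the signal and null
classification checks, 24 patients x 9 tiles for lymphocyte scoring, 16
patients for the interpretability experiments, and n = 300 samples x
2000 genes for expression — sizes at which every planted effect is
recoverable and the whole analysis runs on one CPU core in minutes.

## Known limitations

- The numpy CNN is deliberately small; it is a vehicle for the analysis
  logic (weak supervision, voting, interpretability), not a competitive
  histopathology backbone.
- The null-control AUC check averages 3 replicate cohorts because a
  single 20-patient evaluation has an AUC standard deviation of ~0.13
  under the null.
- Probabilities of lightly trained models are poorly calibrated; argmax
  accuracy on near-chance tasks can sit exactly at the class prior while
  AUC is informative. Patient-level AUC is the primary metric throughout.
- Segmentation is tuned to the generator's appearance model (dark nuclei
  on pale background); real H&E would need stain normalization and a
  re-tuned threshold/watershed.
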