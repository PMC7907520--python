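# Methods

## Problem and pipeline

`radiomap` implements a radiogenomics classification pipeline for
predicting a binary genotype — EGFR mutation status of a lung
adenocarcinoma, EGFR(+) vs EGFR(−) — from a table of CT radiomics
features. The pipeline transforms a wide tabular problem into a small
image-classification problem:

1. **Selection.** Every feature receives a random-forest
   mean-decrease-impurity (MDI) score: the total Gini-impurity
   reduction from splits on that feature, averaged over the forest and
   normalized to sum to one. The top *k* features are retained.
2. **Mapping.** The selected features are z-scored (statistics from
   the development cohort only) and arranged into a √k×√k matrix by a
   center-out spiral, most important feature at the center. Each
   patient thus becomes a one-channel "image" whose spatial structure
   encodes the importance ranking.
3. **Classification.** A small squeeze-and-excitation CNN (SE-CNN)
   maps the feature mapping to a mutation probability. Ablations (the
   same CNN without SE blocks; a 1D CNN on the rank-ordered feature
   vector) and classical ML baselines (SVM / RF / MLP on the top-50
   features, SVM on clinical covariates, SVM on both) provide
   reference points.

The feature *extraction* step (texture matrices, wavelet and LoG
filtering of voxel data) is deliberately out of scope: the package
consumes feature tables in the `<channel>_<group>_<Metric>` naming
convention and never touches images.

## Feature taxonomy and catalog

Features are indexed by (channel, group, base metric): 12 channels
(original, 8 wavelet decompositions LLL…HHH, LoG at σ = 1, 2, 3 — σ in
voxel units, smaller σ emphasizing finer texture) × 6 groups (shape,
firstorder, glcm, gldm, glrlm, glszm), with shape restricted to the
original channel since geometry is filter-invariant. The per-group
metric roster is configuration; the default is a standard
pyradiomics-style roster giving 1,070 names. No fixed total is
enforced because the roster varies across extractor versions.

## The SE block

For a feature tensor U with channels u_1…u_C over an H×W plane:

* squeeze: z_c = (1/HW) Σ_ij u_c(i,j) — a global channel descriptor;
* excite: s = σ(W₂ δ(W₁ z)) with δ = ReLU, σ = the logistic sigmoid,
  W₁ ∈ ℝ^(C/r×C), W₂ ∈ ℝ^(C×C/r), no biases; r is the bottleneck
  reduction ratio (default 8);
* scale: x̃_c = s_c · u_c.

The excitation gate must map into (0,1) for the block to recalibrate
rather than rectify channels, so the output nonlinearity is a sigmoid
and the bottleneck nonlinearity is the ReLU — the standard SE
formulation.

## Architecture and training

Default 2D stack (all sizes exposed in `ConvStackConfig`):
conv 3×3×32 (same padding, ReLU) → SE(r=8) → 2×2 max pool →
conv 3×3×64 → SE(r=8) → 2×2 max pool → flatten → dropout 0.5 →
dense 64 (ReLU) → dense 1 (sigmoid). The plain CNN is the identical
stack without the two SE blocks; forcing the SE gates to 1 makes the
two networks pointwise identical given shared weights, which is tested.
Exactly two convolutional layers are used: with development cohorts of
well under a thousand patients, deeper stacks overfit. The 1D ablation
is conv 7×32 → max pool 2 → conv 7×64 → global average pool →
dropout → dense 64 → dense 1; its layer sizes are this package's
choice, config-exposed, since only the layer-kind skeleton (two
convolutions, one max pool, one average pool) is fixed.

The loss is binary cross-entropy, loss = −Σ[ŷ log y + (1−ŷ) log(1−y)]
in natural log, with probabilities clipped at ε = 1e−7; the analytic
per-sample gradient −(ŷ/y − (1−ŷ)/(1−y)) is verified against central
finite differences. Optimization is Adam with batch size 50 and
learning rate 0.001. Early stopping monitors validation loss with
patience 5 (strict improvement, no minimum delta): training stops
after 5 consecutive non-improving epochs or at `max_epochs`
(default 200), and the best-validation weights are restored. The
development cohort is split 80/20 into training/validation, stratified
by label. Input standardization is per-feature z-scoring before
mapping; the "batch-normalization" reading as a network layer was
rejected because features on wildly different scales (volumes vs
entropies) need per-feature statistics regardless, and a shallow net
on 28×28 inputs gains little from internal normalization layers.

The network is implemented directly in NumPy (im2col convolutions,
float64 throughout, exact backpropagation). Every layer's backward
pass and the full composite gradient are tested against central finite
differences at ~1e−6 relative tolerance. All randomness (weight
initialization, batch shuffling, dropout masks) flows from one seeded
generator, so training histories are bit-reproducible.

## Spiral layout

The documented, invertible arrangement: start at 0-based cell
(side//2 − 1, side//2 − 1) for even side and the exact center for odd
side; first step right; counterclockwise turns (right → up → left →
down in image coordinates) with run lengths 1, 1, 2, 2, 3, 3, …;
cells outside the grid are skipped (unavoidable near the border for
even sides). Skipping preserves the key invariant, proven by test for
all sides 1…30: the Chebyshev ring distance from the start never
decreases with rank, so importance decays monotonically from center
to edge. Any fixed bijection with this property satisfies the design
intent; the layout is persisted (rank, row, col, feature name) with
every checkpoint so mappings are reconstructible. The mapping side
must satisfy side² = k — alternative sizes (24×24, 32×32) are
alternative configurations, not padded variants.

## Splits and leakage control

Cohorts are split into a development set and held-out test set(s)
(default test fraction ≈ 0.1, mirroring a 638/71 design; an external
cohort can be evaluated from the persisted checkpoint). Feature
selection and normalization statistics are computed on the development
rows only — `rf_importance` accepts the split object and restricts
itself, and `fit_normalizer` takes an explicit id list — so test
patients cannot influence which features are used or how they are
scaled.

## Classical baselines

scikit-learn estimators with fixed hyperparameters: SVM (RBF, C=3,
γ=1), random forest (4 estimators), MLP (hidden layers (10, 5), ReLU,
Adam). Radiomics baselines consume the top-50 z-scored features
(k=50 follows the ~10-patients-per-feature rule of thumb for a
development cohort of several hundred). Clinical covariates are
encoded as gender (male=1), z-scored age (training statistics), and an
8-category one-hot histopathological subtype that is all-zero for
cohorts lacking subtype annotation. SVM scores for ROC are the signed
decision function — AUC is rank-based, so calibration is unnecessary —
with the hard-label cut at 0.

## Evaluation

AUC is computed in Mann–Whitney form via midranks,
P(s⁺ > s⁻) + ½P(tie), and is checked against exhaustive pair counting.
Threshold metrics (accuracy, recall, precision, F-score, confusion
matrix) use a 0.5 probability cut (0 for decision-function scores)
with EGFR(+) as the positive class; undefined precision (no positive
predictions) is reported as 0 with an explicit flag. Per-feature class
comparisons use the classical equal-variance two-sample t-test
(two-sided; Welch available via `equal_var=False`).

## Synthetic cohorts

Real genotyped CT cohorts are private, so the generator produces the
statistical skeleton the pipeline assumes: n patients × p unit-variance
Gaussian features in equicorrelated blocks (default block size 10,
ρ = 0.3 — radiomics features are heavily redundant), with
`n_informative` features carrying a class-mean shift of `effect_size`
pooled SDs, spread evenly across the catalog. Defaults (n=700,
p=1000, 30 informative at d=1.5, balanced classes) match the scale the
pipeline is designed for: ~700 patients, ~1,000 features, a few dozen
genuinely discriminative ones. Clinical covariates are label-uninformative by
default (age ~ N(60, 10²); gender association configurable via
`gender_assoc`).

What passing tests on these cohorts show: the pipeline recovers
planted multivariate signal, ranks genuinely informative features
highly, and produces chance-level AUC under label permutation. What
they do not show: performance on real CT radiomics, whose marginals
are skewed and heavy-tailed, whose correlation structure is far from
block-equicorrelated, and whose class effects are weaker and
interact — the synthetic AUC is an upper bound of convenience, not an
estimate of clinical performance. The clinical AUC values themselves
are not reproducible without the private cohorts.

## Numerical choices and degenerate inputs

* Importance ties break by ascending feature name, making rankings
  platform-reproducible; a forest that never splits yields the uniform
  ranking rather than a division by zero.
* Column permutation invariance is guaranteed (and tested) at the
  ranking level; raw forest importances are not exactly
  permutation-equivariant because per-node feature subsampling is
  index-dependent.
* Zero-variance features abort normalizer fitting rather than being
  silently dropped.
* Missing feature values are rejected at load — the cohort design
  excludes patients whose features cannot be extracted, so imputation
  would misrepresent the cohort.
* Probability clipping at 1e−7 bounds the BCE loss and gradient.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the protocol at full
cohort scale (n=700, p=1000, 28×28 mapping, 500-tree selection forests,
batch-50 training with patience 5). Selection power and null
calibration are averaged over 20 seeded replicates in the test suite
and 5 in the acceptance script; unit tests exercise the same code
paths on small cohorts (tens of patients, sides 3–8) where oracles can
be enumerated by hand.

## Known limitations

* No transfer-learning comparators, Grad-CAM saliency, or
  segmentation/extraction stages.
* The 1D-CNN layer sizes and the SE reduction ratio are package
  choices; conclusions about those ablations are conditional on them.
* Single train/validation split rather than cross-validation; with
  ~700 patients the held-out estimates carry wide confidence bands.
* The generator's Gaussianity means calibration of predicted
  probabilities on real data is untested.
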