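# Methods

## Overview

The package implements a cohort-aggregation analysis for patch-based cancer
detection. Its pipeline: (1) assemble balanced, patient-disjoint resampled
sub-datasets per cohort; (2) train patch classifiers under a fixed-iteration
epoch protocol with validation-accuracy early stopping; (3) aggregate patch
probabilities into slide-level likelihood-ratio decisions and AUROCs;
(4) build four cohort-similarity matrices (cross-cohort detection AUROC and
three cohort-discrimination confusion matrices); (5) cluster cohorts by
Ward's method on the matrices' column vectors, cut the dendrogram into S
super-cohorts, train one detector per group, and (6) select partitions whose
mean AUROC clears the cohort-specific reference's lower 95% confidence
bound, reporting the cheapest and the best.

## Sub-dataset construction

Each cohort contributes `n_subdatasets` (default 5) independently resampled
splits of `n_train_pos + n_train_neg` training and
`n_heldout_pos + n_heldout_neg` held-out slides (defaults 18 each at full
scale). Three criteria hold within every sub-dataset: train and held-out
sets are patient-disjoint; at most one positive and one negative slide per
patient (max two slides per patient); the held-out set is halved into
validation and test with equal class counts, stratified by class within
cohort (the stratification choice is ours; only balance is required).
Slides may recur between sub-datasets but never within one. The counting
identities follow directly: 12 cohorts × 5 sub-datasets × (36+36) slides =
4,320 slide slots; cohort-discrimination training uses 18 slides per cohort
(negative or positive condition) or 36 (general), and their evaluation
consumes 100 patches/slide × 9 (or 18) validation slides × 12 cohorts × 5
sub-datasets = 54,000 (108,000) patches.

## Patch model and training protocol

The classifier is a one-hidden-layer softmax MLP (32 hidden ReLU units,
Adam, learning rate 1e-3) over 14 fixed texture descriptors per patch:
per-channel means and standard deviations, five log radial spectral-band
energies of the luminance, the dark-pixel fraction, and mean
vertical/horizontal gradient magnitudes. Descriptors are standardized by
the training stream's statistics and winsorized at ±3 standard deviations;
the clipping makes a model evaluated far outside its training distribution
respond neutrally instead of arbitrarily, which matters for cross-cohort
transfer. Penultimate features are the hidden activations. The architecture
is intentionally modest — the analysis contract is the training protocol,
not the network: one epoch is `iterations_per_epoch` minibatches of
`batch_size` patches sampled with replacement (32,000 patches/epoch at the
full-scale profile), validation accuracy is measured on
`val_patches_per_epoch` randomly sampled validation patches after each
epoch, and training stops at the first epoch after which the best
validation accuracy has not improved by more than `tol` for
`patience_epochs` (default 5) consecutive epochs. Every patch's label is
its slide's label (detection) or its cohort (discrimination); the latent
per-patch cancer state is never consulted, so positive-slide patch labels
are noisy by design and patch accuracy is capped near
`1 - (1 - tumor_fraction)/2` on balanced streams.

Two profiles exist: `full` (1000 iterations/epoch, 6,400 validation
patches, tol 0) and `desk` (50 iterations/epoch, 512 validation patches,
max 30 epochs, tol 0.005). The desk tolerance is half a percentage point
because a 512-patch accuracy estimate has standard error ≈ 0.02; with tol 0
that sampling noise keeps resetting the patience and epoch counts stop
measuring convergence.

Augmentation (applied to training patches only, in this order): rotation by
multiples of 90° and horizontal flips (exact, no interpolation), additive
brightness jitter (max 64/255), additive saturation (≤ 0.25) and hue
(≤ 0.04) jitter in HSV space, multiplicative contrast about the per-channel
mean (≤ 0.75), with pixels clipped to [0, 1]. Hue/saturation are defined in
HSV and contrast about the mean because the bounds are conventional jitter
magnitudes without accompanying formulas; these are the standard
definitions. The photometric chain is fused into a numba kernel with a
pure-numpy fallback (equivalence is tested to 5e-6).

Randomness: one master seed fans out through named `SeedSequence` spawns to
weight initialization, minibatch order, augmentation, and validation
sampling. A super-cohort model's seed depends only on (master seed, member
set, sub-dataset index), so the S = N singleton sweep is bit-identical to
the single-cohort path, S = 1 to the universal path, and groups shared
between cuts can be cached without changing any result.

## Slide inference

With normalized patch probability rows, slide confidences are channel-wise
sums `p̂_y = Σ_patches p_y` (so `Σ_y p̂_y = n_patches`); the decision is the
likelihood-ratio test `ŷ = 1{p̂_1/p̂_0 ≥ η}` with `p̂_0 = 0, p̂_1 > 0`
deciding positive for any finite η. For thresholdless evaluation the score
`p̂_1/(p̂_0+p̂_1)` is used: strictly increasing in the ratio, hence
rank-equivalent — the ROC from score-ranking equals the ROC from an
exhaustive η sweep (tested against a brute-force sweep oracle). AUROC is
the normalized Mann–Whitney statistic with ties credited 0.5
(scikit-learn's implementation, verified against exhaustive pairwise
counting). The original formulation sums pixel-wise fully-convolutional
outputs over the slide domain; with a bag-of-patches representation the sum
runs over patches — the same slide-level contract.

## Similarity matrices and aggregation

Matrix orientation is rows = origin/target cohort *i*, columns =
source/predicted cohort *j*; the semantics strings are carried in the type.
All similarity evaluations use validation (not test) slides, reserving test
slides for the final partition evaluation. Discrimination confidences are
averaged at the patch level, pooled across sub-datasets (a per-slide-mean
variant is available via flag). Ward clustering runs on the Euclidean
distances between column vectors via `scipy.cluster.hierarchy.ward`;
cutting at S undoes the S−1 highest merges (union-find over the first
N−S linkage rows). The brute-force Ward oracle in the test suite
re-derives every merge from the within-cluster variance objective from
scratch and agrees with the linkage heights and all cut partitions over 100
random matrices.

`evaluate_partition` scores each cohort with its group's model on that
cohort's test slides, averages AUROC over sub-datasets, and reports the
mean over cohorts with a t-distribution 95% confidence halfwidth
(`t_{0.975, n−1}·sd/√n` over the per-cohort means; alternatives — over
sub-dataset means or all cohort×sub values — were considered and not used).
Training time is counted in epochs, never wall-clock, for hardware
independence. The selection gate is one-sided by default (mean AUROC ≥
reference mean − halfwidth); a stricter two-sided variant is exposed as a
flag. Ties break toward smaller S, then matrix-kind order C, D_n, D_p, D_g.
The sweep enumerates every matrix kind × S by default, reconstructing the
end-to-end procedure: cut, train per group per sub-dataset, evaluate,
select.

## The synthetic generator

The generator replaces an unavailable multi-slide imaging corpus with
procedural RGB textures whose *statistical* structure matches what the
analysis consumes. Twelve texture parameters (θ) control per-channel base
color, spectral band center and width, blob rate/radius/darkness,
per-channel texture amplitude, and orientation anisotropy; a patch is a
colored background plus oriented band-pass noise plus dark nuclei-like
blobs, clipped to [0, 1]. θ is mapped through a sigmoid into each
parameter's bounded range, with frequency expressed as a fraction of
Nyquist and blob count proportional to patch area so a θ means the same
texture at any patch size.

Cohort relatedness is planted: θ evolves by Brownian motion along a rooted
tree (per-branch variance `sigma_walk² × branch length`), so
`E‖θ_i − θ_j‖² = dim × sigma_walk² × path(i, j)`. Cancer perturbs a
positive patch's *rendering parameters* by `cancer_effect × 10%` of each
parameter's range along a unit direction; operating in render space keeps
the perturbation equally perceptible in every cohort regardless of where θ
sits on the sigmoid. The direction mixes a shared global component (weight
`shared_cancer_weight`, default 0.3) with a cohort-specific component built
from per-tree-node vectors weighted by √branch-length (the Brownian-bridge
decomposition); node vectors are orthogonalized when the dimension allows,
so the cosine between two cohorts' directions is a deterministic increasing
function of their shared tree path — related cohorts share cancer
morphology, distant cohorts get nearly orthogonal perturbations. Positive
slides carry exactly `round(tumor_fraction × patches_per_slide)`
latent-cancer patches (default tumor fraction 0.7 — tumor purity is not
otherwise constrained, and 0.7 makes the noisy-label limitation
exercisable); all patches inherit the slide label.

Defaults emulate a balanced corpus at desk scale. The canonical test
fixture (`supercohort.fixtures.three_pair_config`) plants three
near-duplicate pairs (pair merges at height 0.02, upper merges at 4 and 6;
`sigma_walk` 0.5 so θ stays in the responsive rendering range) with 40+40
slides per cohort, 12 patches of 16×16 px per slide, 5 sub-datasets of
12+12 training and 16+16 held-out slides. Near-duplicate pairs mirror the
motivating situation of cohorts so similar a classifier cannot separate
them; the 40-slide pools keep the five per-cohort sub-models from sharing
one idiosyncratic small pool, which would otherwise make twin cohorts'
cross-cohort transfer profiles diverge.

What the generator does **not** emulate: realistic H&E appearance, stain
variation, spatial correlation between patches of a slide beyond shared
parameters, scanner or site batch effects, heterogeneous slide counts, or
intra-tumor heterogeneity. Passing tests therefore show the *analysis
machinery* is correct and that the pipeline recovers planted structure
under controlled conditions — not that the metrics would resolve any
particular real tissue relationships.

## Numerical and design notes

* Ward ties: scipy's nearest-neighbor-chain algorithm is deterministic;
  exact ties are measure-zero on real-valued matrices and not specially
  tie-broken.
* Degenerate inputs: single-class AUROC raises; empty patch streams raise;
  `p̂_0 = p̂_1 = 0` cannot occur with normalized rows but is guarded;
  slides with fewer patches than an evaluation budget are resampled with
  replacement with a warning.
* Early stopping monitors accuracy for all tasks (detection included), with
  the brute-force saturation-rule replay tested on 1,000 synthetic traces.
* The cross-cohort detection transfer of near-identical cohorts is
  inherently the noisiest similarity signal (a model's behavior far outside
  its training distribution is chaotic in its training pool); descriptor
  winsorization and the fixture's pool sizes control, but do not eliminate,
  this — the planted-recovery guarantee is statistical (≥ 4/5 seeds), not
  per-seed.
* UMAP embedding of penultimate features (n_neighbors 20, min_dist 0.5,
  20 sampled patches/slide) is optional and purely qualitative; nothing
  downstream depends on it, and it is skipped with a log message when
  umap-learn is absent.
* Desk-scale problem sizes (16×16 patches, 50-iteration epochs, the fixture
  sizes above) are the package's chosen study conditions; the full-scale
  profile retains the reference protocol constants.
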