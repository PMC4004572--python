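# Methods

This note documents the models, conventions and design choices behind
`lesionbench`, in the spirit of a statistical software methods appendix.
It states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic multimodal MRI model

Each study is a deterministic function of `(seed, subject_index)` via
independent `numpy` `SeedSequence` substreams; regenerating a cohort with
the same config is bit-exact.

**Anatomy.** The brain is an ellipsoid (semi-axes 0.42/0.37/0.33 of the
grid) whose normalized radius is perturbed by smooth Gaussian random fields
(correlation length 3–4 voxels) before thresholding, giving irregular
tissue boundaries: a gray-matter shell outside normalized radius ~0.80, a
white-matter core inside it, and an elongated central "ventricle" of CSF.
The grid is 64³ at 1 mm isotropic by default — large enough that the 41³
smoothing window is small relative to the brain, small enough for desk-scale
experiments.

**Lesions.** A Poisson(8) number of lesions per subject (minimum 1) are
planted at white-matter locations sampled with probability ∝ exp(−d/8 mm)
of the distance d to the ventricle, emulating periventricular predominance.
Each lesion is a sphere of radius U(1.5, 4) mm whose boundary is modulated
by a shared smooth deformation field (±35%), intersected with white matter.
Single-voxel fragments are deleted, so every lesion is a connected
component of ≥ 2 voxels, matching the clustered-lesion assumption behind
the local-moment features. After placement the generator compares the
lesion fraction against `lesion_fraction_target` (default 0.01 of the
brain-tissue mask, the ~1% prevalence regime of MS cohorts); if it misses
by more than 50% the count is rescaled and placement redrawn once — a
bounded, seed-deterministic calibration rather than an open-ended loop.

**Intensities.** Voxels take per-tissue mean values (arbitrary units):

| modality | CSF | GM  | WM  | lesion |
|----------|-----|-----|-----|--------|
| T1-w     | 40  | 90  | 120 | 70     |
| T2-w     | 180 | 120 | 100 | 150    |
| FLAIR    | 50  | 105 | 100 | 160    |

so lesions are FLAIR/T2 hyperintense and T1 hypointense, and CSF is
FLAIR-dark (which is what makes the 15th-percentile brain-mask rule remove
it). Each modality of each subject is then perturbed by a global affine map
with gain U(0.7, 1.3) and offset U(−40, 40) — MRI intensity units are
scanner-arbitrary, and this is what makes raw intensities non-comparable
across subjects — followed by i.i.d. Gaussian noise (σ = 15). With these
values the FLAIR lesion-versus-WM contrast of the weakest-gain subject is
~2.8 noise SDs, which puts roughly 95% of lesion voxels above the
85th-percentile candidate threshold and yields the ~6× lesion enrichment
that voxel selection is supposed to provide. There is no multiplicative
bias field: the generator emits data in the state real pipelines reach
*after* inhomogeneity correction, because registration, bias correction and
skull stripping are explicitly out of scope (the extracerebral mask is an
output of the generator).

**What the generator does not emulate.** Real anatomy (gyri, partial
volume, tissue texture), scanner artifacts, anisotropic acquisition,
rater variability in the manual reference, and spatially correlated noise.
Passing tests therefore demonstrate that the pipeline's *relative* claims
(features matter more than classifiers; downsampling is safe) reproduce
under the stated statistical structure — not that any absolute performance
number transfers to clinical data.

## Preprocessing

The brain-tissue mask keeps extracerebral-mask voxels whose FLAIR intensity
is at or above the empirical 15th percentile of FLAIR over that mask
(linear-interpolation quantile; removal is strict, ties survive). The
percentile is computed per subject — the only reading compatible with a
single-subject pipeline. On continuous intensities this retains 85% of
voxels by construction; the CSF removal is emergent from FLAIR darkness.

## Feature extraction

* **Normalization**: standard scores over the brain-tissue mask using the
  sample SD (divisor n−1); exactly invariant to per-subject affine
  intensity maps with positive gain.
* **Candidate selection** operates on the *normalized* FLAIR (normalization
  precedes selection in the pipeline's dataflow) with an "at or above"
  85th-percentile rule.
* **Gaussian smoothing**: separable kernel with σ = n/4 voxels, hard
  truncation to the n×n×n window. The window sizes (21, 41) are the
  specified quantities; σ = n/4 is this package's convention placing ±2σ at
  the window edge. Smoothing is mask-renormalized —
  out(v) = ΣK·x·m / ΣK·m — so constants are reproduced exactly inside the
  mask and no intensity bleeds across the mask boundary. The denominator is
  never zero for v in the mask (v lies in its own window).
* **Local moments**: raw (non-central) k-th sample moments of normalized
  intensities over the window intersected with the mask, k ∈ {1,2,3},
  n ∈ {3,5}. Mask intersection mirrors the smoothing contract; whether to
  zero-pad instead is undocumented in the source procedure, and the masked
  variant was chosen for consistency.
* **Column order** is fixed: normalized block (t1, t2, flair), then
  smoothed block (modality-major, window ascending), then moments block
  (modality-major, k ascending, window ascending).
* Voxels excluded by candidate selection are excluded from training rows
  and receive predicted probability 0 at inference, so validation is always
  defined on the entire brain volume.

## Classifiers

All nine algorithms implement `fit(features) / predict_proba(features)`
with probabilities in [0, 1]. Standard estimators come from scikit-learn;
the stacking logic, tuning loop and evaluation metrics are implemented
here. Non-default numerical choices:

* **Tuning loss**: mean held-out scaled pAUC (FPR ≤ 0.1) over 10 stratified
  CV folds — the benchmark's own outcome metric. Folds are stratified
  because at ~1% prevalence unstratified folds can be lesion-free.
  Ties break toward the earlier grid point. A k-NN grid point whose k
  exceeds the fold training size is skipped with a warning.
* **Logistic regression**: unpenalized MLE with tight tolerance (1e−8), so
  the score-equation identity (mean fitted probability = prevalence) holds
  to ~1e−6.
* **QDA**: covariance ridge `reg_param = 1e-3` — with tens of lesion voxels
  in up to 27 dimensions the class covariance is otherwise near-singular.
* **Gaussian mixture**: per-class mixtures, components 1–9 and covariance
  model (spherical/diagonal/full) chosen by BIC, but a combination is only
  admitted when the class has enough samples to identify it (full
  covariance requires ≥ (d+2) samples per component). `reg_covar = 1e-3`
  on unit-scale (z-scored) features. Posteriors are computed in clipped log
  space: without the identifiability gate, degenerate density spikes
  produce log-likelihood ratios of ~10⁶ whose exponentials underflow into
  rank-destroying ties.
* **Linear SVM**: `LinearSVC` over the seven-point cost grid with
  Platt-style calibration — a 1-D logistic fit to training decision values.
  The calibrator keeps a mild L2 penalty so it remains finite on separable
  margins; calibrated probabilities are monotone in the margin, so ranking
  metrics are unaffected.
* **Neural network**: one hidden layer (sizes 1/5/10), logistic
  activations, seeded initialization, iteration cap 200 with adam's plateau
  stopping — a fixed budget that converges at these problem sizes.
* **Random forest**: 500 trees, `max_features = mtry` swept over 1..d.
* **Super learner**: the library enumerates every grid point of every base
  algorithm (17 + d members), matching the per-tuning-parameter weight
  structure the stacked ensemble is meant to expose. Meta-learning is
  non-negative least squares of the labels on the level-one matrix with
  simplex renormalization — the canonical squared-error choice for
  probability stacking; an all-zero NNLS solution falls back to uniform
  weights with a warning. `fit_suite` shares the fold fits between grid
  tuning and the level-one matrix, so each (algorithm, grid point) is fit
  exactly once per fold; this changes no estimate, only the bookkeeping.

## Evaluation

Empirical ROC curves pool all validation voxels across subjects (single
curves per method are reported, and per-subject averaging is deliberately
not done); tied scores are grouped into single steps, which is equivalent
in expectation to randomized tie-breaking, and makes the full-range scaled
pAUC coincide exactly with the Mann–Whitney statistic with half-credit
ties. Partial areas use trapezoidal integration with linear interpolation
at the FPR bound. The segmentation threshold is the smallest score whose
*pooled* FPR is ≤ 0.5% (per-subject thresholds are a defensible alternative
the source procedure does not describe); if even the top score is a false
positive the threshold is +∞, i.e. the empty segmentation. Dice of two
empty sets is defined as 1 with a warning; the case never arises in the
experiments.

## Experiment scales

The default configuration is desk-scale: 20 generated subjects split 10/10
into training and validation, 500 uniformly sampled brain-mask voxels per
training subject (a 5,000-voxel pool, ~1% lesion), and a downsampling grid
of 1,000–5,000 voxels in steps of 1,000 counted *before* candidate
selection, with nested subsets so learning curves differ only through added
rows. These sizes preserve the qualitative structure of the full-scale
design (49/49 subjects, 24,500 voxels, grid to 24,000), which remains
available through `ExperimentConfig`. The downsampling harness defaults to
a four-algorithm subset (logistic regression, LDA, Gaussian mixture, k-NN)
— learning-curve stability is a property of the feature space, and these
four span linear, quadratic and non-parametric decision boundaries while
keeping the grid sweep tractable on one CPU; any subset, including all
nine, can be requested. Fit and prediction timings are recorded in the
results table for reporting but never asserted, being hardware-dependent.

## Known limitations

* The phantom's tissue model is piecewise-constant plus noise; texture-
  driven false positives (e.g. cortical GM mimicking lesions on FLAIR) are
  underrepresented, which flatters all classifiers roughly equally.
* σ = n/4 is a convention; other bandwidths for the same window sizes would
  change smoothed-feature values (not the pipeline contracts).
* The super learner's library grows linearly with feature dimension via the
  random-forest mtry grid, which dominates its fit time in high-dimensional
  kinds.
* Probabilities from the clipped-log-space Gaussian mixture saturate for
  voxels whose density ratio exceeds e⁷⁰⁰; ranking below saturation is
  preserved.
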