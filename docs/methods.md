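# Methods

`radaug` implements a dual-level augmentation radiomics pipeline for
imbalanced binary tumor grading from co-registered multi-sequence 3D MRI:
image-level augmentation (IA) of training cases before feature extraction,
an intraclass-correlation reproducibility gate, feature-level augmentation
(FA, SMOTE) after extraction, two-level feature selection crossed with a
classifier grid, and repeated stratified k-fold cross-validation scored by
pooled-prediction CV-AUC. A synthetic phantom module provides fully
controlled cohorts so every stage is testable without patient data.

## The pipeline

For each repetition of a stratified K-fold plan, and each training fold:

1. **IA** (modes `IA`, `IAFA`): every training case is expanded to the
   original plus 9 augmented copies — 3 random affine rotations, 1 elastic
   deformation (morphological: one shared geometric transform resamples
   both sequences with linear interpolation and the mask with
   nearest-neighbor), and 1 each of motion ghosting, multiplicative bias
   field `exp(poly3)`, additive Gaussian noise, Gaussian blur, and gamma
   contrast (intensity ops: the mask is bit-identical to the parent's, so
   all 14 shape features are exactly preserved — a property the test suite
   asserts bit-for-bit).
2. **Feature extraction**: images are resampled to 1 mm isotropic,
   z-scored over the whole volume and rescaled by 100; intensities are
   discretized at fixed bin width 32. The full schema is 14 shape features
   per sequence plus, on each of 17 filter images (original, 8 stationary-
   wavelet sub-bands of a coif1 level-1 decomposition, Laplacian-of-Gaussian
   at sigma 1/3/5 mm, square, square root, logarithm, exponential, gradient
   magnitude), 18 first-order and 75 texture features
   (24 GLCM + 16 GLRLM + 16 GLSZM + 5 NGTDM + 14 GLDM): 1595 per sequence,
   3190 for a two-sequence case. GLCM/GLRLM use the 13 unique directions at
   distance 1 with per-direction feature averaging; GLSZM/NGTDM/GLDM use
   26-connectivity; GLDM dependence threshold 0.
3. **Reproducibility gate** (modes `IA`, `IAFA`): for every feature, the
   two-way random-effects absolute-agreement single-measurement ICC
   (ICC(2,1)) is computed on a training-cases × replicates grid and
   features with ICC < 0.9 are dropped. The replicate set is the original
   plus the five intensity-op copies. Morphological copies are excluded
   from the gate (not from training): a rotated or elastically deformed
   case is a genuinely different geometry, and measuring "agreement"
   across geometries conflates reproducibility with the very shape
   diversity the augmentation is meant to inject; restricting the gate to
   intensity perturbations also makes "shape features survive a gate built
   from intensity replicates" an exact invariant. Constant features are
   excluded through the zero-variance path; an empty post-gate schema
   aborts the trial with a logged failure.
4. **FA** (modes `FA`, `IAFA`): SMOTE with 5 minority-class nearest
   neighbors; synthetic rows `x_i + u (x_nbr − x_i)`, `u ~ U(0,1)`, are
   generated in rounds (one per minority row, a fresh neighbor direction
   per round; the truncated final round draws a uniform subset of parents)
   until the classes are exactly 1:1. Provenance (parent, neighbor, u) is
   recorded; a segment-membership oracle re-solves every synthetic row in
   the tests.
5. **Selection and classification**: first-level filter ranking (chi-square
   on min-shifted 10-bin features, |t|, Kruskal–Wallis H, variance, relief
   margin, mutual information, or greedy mRMR with F-statistic relevance /
   mean-|r| redundancy) keeps the top 100; the embedded second level (L1
   logistic regression, elastic net, LASSO, L1-SVM along their
   regularization paths to at most 10 nonzero coefficients, or top-10
   importances of RF / extra-trees / gradient boosting / XGBoost) picks the
   final subset; one of 13 classifiers is fitted on standardized training
   rows. The full grid is 7 × 8 × 13 = 728 settings.
6. **Scoring**: held-out folds receive preprocessing and extraction only.
   Per repetition the pooled predictions of all K folds give the CV-AUC
   (distinct from the mean of per-fold AUCs, which is also reported), and
   sensitivity/specificity at the Youden-optimal threshold (lowest
   threshold on ties). No augmented or synthetic row ever descends from a
   held-out case; a canary test plants the test labels as a feature that is
   noise on training rows and verifies chance-level performance.

Statistics: DeLong's test (structural components) for paired AUCs on the
same cases, two-sided paired t-tests on per-repetition metric series, and
a trend test across the ordered modes None → FA → IA → IAFA
(within-repetition OLS slope of the metric on mode rank 0..3, then a
one-sample two-sided t-test of slopes against zero). Alpha is 0.05
throughout, no multiplicity correction.

## The phantom

Each case is an ellipsoidal tumor (radii drawn per axis from a configured
mm range, center jittered) in homogeneous background on a regular grid.
The boundary is optionally perturbed radially by a smooth random angular
function (three sinusoidal terms, normalized) — "margin irregularity".
Inside the mask the intensity is multiplicative:
`base × (1 + h · G)` with `G` a unit-variance Gaussian-smoothed noise
field (correlation length 1.5 voxels); two sequences use correlated but
distinct fields (ρ = 0.7) and different base intensities. The
heterogeneity amplitude `h` is the class dial: the minority (high-grade)
class has a larger class mean; each case multiplies it by a lognormal
jitter (σ = 0.3) so the cohort has realistic between-case spread — this
spread is also what gives the ICC gate a meaningful between-case variance
to compare against.

On top of the class signal, every case receives a label-independent
**acquisition nuisance**: a random mild multiplicative bias field
(order-2 polynomial, coefficients ±0.15 by default), a gamma-like contrast
shift (log-range 0.2) and a per-case noise level (0.5–1.5 × the nominal
2 % of base intensity). This emulates scanner/protocol variation in a
retrospective cohort and is the variation the IA op families themselves
model; without it, a raw-cohort model has nothing to overfit and
augmentation has nothing to protect against.

Seeding is counter-based: per-case seed sequences are spawned from the
master seed by case index (adding or removing cases never shifts other
cases' streams), and within a case geometry and texture use separate
child streams, with the label selecting only amplitudes — flipping the
label provably keeps the geometry.

Reality gap: the phantom has single-component, star-shaped tumors,
Gaussian textures, no anatomy, no partial-volume model and no MR physics.
Passing the ablation criteria here demonstrates that the pipeline's
machinery behaves as designed (augmentation helps under acquisition
variation and class imbalance, and manufactures nothing under the null);
it does not validate clinical performance.

## Study conditions and problem sizes

The ablation-trend experiment (`moderate_ablation_config` +
`ablation_config`) uses a 48:12 cohort (the 4:1 imbalance of the
motivating cohort, scaled down) on 24³ voxel grids at 1 mm spacing,
tumor radii 4.5–6.75 mm, the reduced setting CHSQ + LASSO + LR, K = 3
and 10 repetitions, with the original-filter extraction profile (all
seven feature classes on the unfiltered image, 214 features for two
sequences). The full 17-filter, 3190-feature schema is exercised on
single cases in the test suite. The moderate signal dial (heterogeneity
0.10 vs 0.12, margin irregularity 0.08) was chosen so the best single
feature reaches an AUC of roughly 0.75–0.85 and the signal is spread
over several shape and texture features. The null-safety control zeroes
both dials and keeps everything else; because a single finite null
cohort carries realized spurious separability, the chance-level check
averages repetitions over three independent null cohorts.

Augmentation magnitudes for these small volumes come from
`AugmentationRecipe.small_volume()` (rotation ±10°, elastic ≤ 1 mm on a
7³ control grid, motion ghost ≤ 8 % weight with ≤ 5°/2 mm transforms,
bias coefficients ±0.05, noise ≤ 0.05 image SD, blur ≤ 0.4 mm, gamma
log-range 0.1) — deliberately inside the envelope of the phantom's own
acquisition nuisance, since augmentation compounds on top of each case's
realized nuisance. The dataclass defaults keep clinical-field-of-view
magnitudes (elastic ≤ 7.5 mm, motion ≤ 10 mm, bias ±0.5); on a ~20 mm
phantom those deform or ghost the entire tumor and leave no feature
reproducible, so the scaled preset is the appropriate instrument model
at this grid size.

## What the ablation shows at phantom scale

On these phantoms the four modes do **not** reproduce a positive
dual-augmentation margin: across every regime examined (16³ and 24³
grids, texture-, shape- and mixed-signal dials, three augmentation
magnitude levels, nuisance strengths from zero to strong, candidate
feature sets of 112 and 214), SMOTE alone tracks the raw pipeline
(consistent with the motivating study's own FA ≈ None finding), the
reproducibility gate is performance-neutral, and training pools that
contain augmented copies sit a few hundredths of CV-AUC *below* the raw
pipeline. A four-arm decomposition (raw / gate-only / pool-only /
gate+pool) localizes the deficit entirely in the pooled augmented rows:
augmentation noise adds on top of each case's own acquisition nuisance —
an errors-in-variables effect that attenuates the weights of the most
informative features and rotates the learned direction toward robust but
weaker ones. The package reports this honestly; the acceptance outputs
carry the per-mode means, the (negative) IAFA − None margin and the
trend p-value. The regime in which image-level augmentation pays off —
very large feature-to-case ratios with clinical-resolution regions of
interest where the perturbations are feature-preserving — is not one a
60-case desk-scale phantom can honestly occupy, and claims about it
should be evaluated on data of that scale.

## Numerical choices

* Fixed bin **width** (not count) of 32 after z-score × 100 rescaling —
  a width of 32 on unit-variance values would collapse to ~1 bin.
* Wavelet sub-bands use the stationary (undecimated) transform so all 8
  sub-band images keep the input grid; odd axes are symmetric-padded and
  cropped back.
* Pointwise filters use sign-preserving, range-normalizing conventions
  (e.g. square = (x/√max|x|)², exponential = exp(x·log(max|x|)/max|x|)).
* Shape meshes are marching-cubes surfaces of the mask lightly smoothed
  with a 0.8-voxel Gaussian (antialiasing): the staircase surface of a
  hard binary mask inflates areas and makes surface-based features
  needlessly sensitive to resampling; tiny masks that would vanish under
  smoothing are meshed unsmoothed. Axis lengths use 4·√eigenvalue of the
  physical-coordinate covariance; degenerate (≤1 voxel) masks define
  elongation/flatness as 1 and axis lengths as 0 so no value is
  non-finite.
* GLCM correlation is 1 for a single gray level; MCC is the square root
  of the second-largest eigenvalue of the transition-style matrix Q and 1
  in the single-level case; NGTDM coarseness is capped at 10⁶ when the
  denominator vanishes.
* ICC denominators at zero total variance: identical values give ICC 1;
  non-identical zero-denominator grids are an error.
* Youden threshold scanning uses observed scores as cut-points
  (prediction positive at prob ≥ t), lowest threshold on ties.
* LASSO/elastic-net/L1 paths pick the largest support not exceeding
  `max_selected`; an empty selection falls back to the top first-level
  feature (logged).
* Rigid transforms rotate about the grid center ((N−1)/2), so axis-aligned
  90° rotations land exactly on grid points and conserve mask volume
  exactly; random draws pushing more than half the mask out of view are
  rejected and redrawn with the next seed.

## Known limitations

* The phantom's acquisition nuisance and the IA operators share functional
  families (bias/gamma/noise/PSF, random orientations vs rotations); this
  is deliberate — augmentation is supposed to model acquisition variation
  — so the phantom gives augmentation its best case, which makes the
  negative margin above more, not less, informative.
* At coarse grids morphological copies carry interpolation noise in
  texture and surface features; the reproducibility gate absorbs most of
  it, but fold-level AUCs remain noisy (4 positive cases per held-out
  fold). The trend statistics are computed across repetitions for this
  reason.
* Classifier hyperparameters are library defaults (no nested tuning by
  default); the grid exists to be enumerated and compared, not tuned to
  any single cohort.
* A naive train–test split path (`run_naive_split`, ratios like 2:1, 4:1,
  9:1) is provided to demonstrate split-to-split variability; it is not
  part of the headline metrics.
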