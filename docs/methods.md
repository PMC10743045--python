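# Methods

`radrobust` studies how the choice of lesion segmentation method propagates
into radiomics features and downstream classifiers, using fully synthetic
3D PET-like cohorts so the whole analysis is reproducible from a seed.
This note records the models, conventions and numerical choices; nothing
here states a result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Synthetic cohort

Each subject is an ellipsoidal "hot" lesion in a uniform background:

* **Geometry.** Two scanner-like voxel grids, 2.73 × 2.73 × 3.27 mm and
  1.45 × 1.45 × 3 mm, mixed 29:49 by default over a 78-subject cohort
  (43 low-grade, 35 high-grade labels).
* **Lesion.** Per-axis radii drawn from 8–13 mm with ±15% anisotropy; a
  two-level core/rim intensity profile (core within 60% of the normalized
  radius; rim at 60% of the core uptake; background 1.0; core ≈ N(10, 1)).
* **Intra-lesion texture.** A Gaussian random field smoothed to a
  correlation length of twice the mean voxel spacing, scaled to unit SD and
  multiplied by a per-subject heterogeneity amplitude ≈ N(1, 0.25). This is
  the parameter that carries the class signal: high-grade subjects have
  their mean amplitude shifted upward by `effect` within-class SDs
  (default 1.5).
* **Noise.** Additive Gaussian noise (SD 0.5 uptake units) *spatially
  correlated* to a 5 mm FWHM. Reconstructed emission images never show
  voxel-wise white noise; the correlation length is the field-standard
  post-reconstruction resolution. The correlation is exposed as
  `PhantomSpec.noise_fwhm_mm` (0 disables it).

What the generator does **not** emulate: attenuation, scanner PSF applied
to the activity itself (lesion edges stay sharp up to the grid), Poisson
count statistics, reconstruction artefacts, anatomy. Consequences are
visible in the acceptance patterns (below).

The "manual" segmentation of synthetic runs is a boundary-perturbed copy of
the ground truth: the signed Euclidean distance transform is thresholded at
a band-limited random field (6 mm smoothing) scaled to an RMS displacement
of the requested amplitude (default 2 mm), and the component containing the
innermost voxel is kept, guaranteeing a smooth, closed, connected surface.
A perturbation that loses that voxel is retried at half amplitude up to
three times, then fails loudly.

## Segmentation

* **Thresholding**: voxels in a user ROI box at or above a fraction
  (default 0.40) of the ROI's maximum, restricted to the 26-connected
  component containing the maximum voxel. The published description of the
  emulated workflow does not state its percentage; 0.40 is a declared
  assumption, surfaced in configuration. Failure modes: contrast-free ROI,
  empty result, or a mask covering >90% of the ROI (nothing stands out of
  the background).
* **Region growing**: morphological Chan–Vese evolution on the ROI crop,
  initialized from a box shrunk 25% inside the ROI, 60 iterations. The crop
  is pre-filtered with a 0.7-voxel Gaussian; curvature smoothing is off by
  default because morphological smoothing systematically erodes lesions a
  few voxels across (set `rg_smoothing` to re-enable). The brighter phase
  is the lesion. Deterministic; fails on contrast-free ROIs.
* **Agreement**: Jaccard index J(X,Y) = |X∩Y|/|X∪Y| averaged over subjects
  per method pair; subjects with any failed semi-automatic method are
  excluded cohort-wide before every downstream stage, mirroring how real
  cohorts shrink when semi-automatic methods fail.

## Image preprocessing

Fixed order: z-score normalization of the whole volume (population SD,
scale 1) → resampling to 2 × 2 × 2 mm (cubic B-spline for the image,
nearest neighbour for the mask) → 18 derived images + the original →
per-image discretization. Derived images: Laplacian-of-Gaussian at
σ ∈ {0.5, 1, …, 5} mm (scale-normalized, σ² ∇²G, mirror boundary; sigmas
below half a voxel warn and proceed) and the 8 sub-bands of a single-level
undecimated coif1 decomposition. Sub-band labels are the per-axis filter
sequence in (x, y, z) order; the grouped analyses depend only on the
labelling being consistent. The wavelet transform symmetric-pads by a
margin, filters periodically and crops — identical to symmetric-extension
filtering away from the padding, and exactly invertible, which the test
suite checks as a perfect-reconstruction property (< 1e-6 relative error).

Discretization uses a fixed bin width of 0.25 intensity units, with bin 1
anchored at the masked minimum of each derived image independently
(`level = floor((x − min)/w) + 1`). Whether the emulated workflow
normalized before or after resampling is not documented; normalization
first is the recorded choice.

## Features (1781 per subject and method)

107 features on the original image (14 shape + 93 intensity/texture) and
93 on each derived image: 18 first-order, 24 GLCM, 16 GLRLM, 16 GLSZM,
14 GLDM, 5 NGTDM. The exact name list is pinned in
`src/radrobust/feature_manifest.json`; totals 107 + 10×93 + 8×93 = 1781.

Conventions that change values:

* GLCM: symmetric, distance 1, 13 unique 3D directions, features computed
  per direction and averaged with equal weight (no distance weighting);
  `Ng` in Idn/Idmn is the per-direction count of occupied gray levels.
  MCC uses the similarity `D^-1/2 P D^-1/2`, whose eigenvalue magnitudes
  equal the square roots of the co-occurrence correlation eigenvalues.
* GLRLM: 13 directions, averaged; runs found by an incremental shift
  algorithm validated against a run-walking brute force in the tests.
* GLSZM zones and GLDM dependencies: 26-connectivity, GLDM α = 0 (equal
  levels), dependence = dependent neighbours + 1.
* NGTDM: 26-neighbourhood means over valid in-mask neighbours.
* Degenerate single-level regions: entropies 0, uniformity 1,
  correlation-type features 1, everything finite by construction.
* Shape is mesh-based on the resampled mask. Marching cubes runs on the
  binary indicator smoothed by a 0.8-voxel Gaussian: meshing the raw 0/1
  field produces a staircase surface whose area overestimates a smooth
  boundary by 10–15% (a digitized 10 mm sphere then reads sphericity
  ≈ 0.82; with smoothing ≈ 0.99). Tiny masks that would smooth away fall
  back to the raw mesh. Axis lengths come from the principal components of
  the voxel-centre cloud (length = 4√λ); in-plane maximum diameters are
  computed per slice from voxel centres via convex hulls.

First-order skewness/kurtosis are population moments (kurtosis not
excess-corrected), 0 on constant regions.

## Reproducibility (ICC)

The three segmentation methods act as k = 3 observers in a two-way crossed
design with one observation per cell. The single-measure absolute-agreement
intraclass correlation is

    ICC = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E)),

computed per feature from the ANOVA mean squares and cross-checked in the
tests against a brute-force decomposition (1e-12) and against pingouin's
ICC(A,1) (1e-9). Bands follow the standard reproducibility convention with
left-closed intervals — poor [−∞, 0.5), moderate [0.5, 0.75),
good [0.75, 0.9), excellent [0.9, ∞) — a convention choice, since the
interval endpoints are ambiguous in prose descriptions; a feature at
exactly 0.75 is "good". Estimates can be negative on data; they are
reported raw and banded "poor". Zero-variance features are not computable
and are excluded from summaries (counted separately). Class averages are
plain means of per-feature ICCs within each grouping (class × image kind,
class overall, wavelet sub-band).

## Feature selection

Hybrid descriptive–inferential: rank all features by |point-biserial
correlation| with the binary label (ties broken lexicographically by name;
constant features dropped), then grow a logistic regression along the
ranking. "The model's p-value" is the likelihood-ratio test against the
intercept-only model — the reference description does not name the
statistic, so this is the recorded choice. The first iteration whose
p-value fails to decrease stops the process; the previous prefix is
returned, and the first feature is always accepted. Perfect separation
freezes the selection at the previous prefix (or at the single separating
feature when it happens at m = 1, keeping the subset nonempty). Features
are z-scored before the logistic fits only; the ranking is scale-invariant.
No iteration cap beyond the stopping rule.

## Evaluation

30 × stratified 5-fold cross-validation with a single fold plan shared by
every model and segmentation method, so differences cannot come from
different partitions. Per repetition the five test folds' predictions are
pooled into one confusion matrix and one AUC (continuous scores, midrank
ties), yielding one value of each metric per repetition; an alternative
would average per-fold metrics, but pooling gives exactly one confusion
matrix per repetition. Metrics (percent): accuracy, AUC, sensitivity,
specificity, precision, F-score; the positive class is high grade.
Models and fixed hyperparameters: LDA; RBF-SVM (C = 1, gamma = 'scale');
KNN (k = 5); random forest (100 trees); AdaBoost (50 stumps); one hidden
layer of 16 units for the neural network (max 500 epochs). Features are
z-scored inside each training fold. 95% confidence intervals are
percentile bootstrap intervals of the repetition mean (1000 resamples).
Selection runs once on the full cohort by default — this reproduces the
singleton-selection behaviour of the emulated workflow but leaks label
information into the CV estimate; a leakage-safe per-fold mode can be
composed from the same pieces by re-running the selector inside each fold.

## Statistical battery

Lilliefors normality per group and Levene homogeneity across groups;
Kruskal–Wallis across feature classes (per image kind); Friedman across
the 8 wavelet sub-bands with features as blocks; Friedman across models
(blocks = segmentation × metric) and across segmentations (blocks =
models, per metric) for CV performance. The performance blocking is a
reconstruction — the emulated analysis does not state its blocks — chosen
to match per-metric significance reporting. Significant omnibus tests
(α = 0.05) are followed by Dunn-type pairwise z-tests on mean ranks
(tie-corrected for Kruskal–Wallis; rank-sum SE √(t(t+1)/6n) for Friedman)
with the Dunn–Šidák adjustment p_adj = 1 − (1−p)^m over all unordered
pairs, computed via expm1/log1p to avoid cancellation. p-values below
2.2e-16 are printed as "< 2.2e-16", never 0. Per-feature ICCs share
subjects and are therefore correlated; the battery reproduces the
conventional procedure and carries that caveat here rather than modelling
the dependence.

## What the synthetic cohorts do and do not show

Passing patterns on phantoms demonstrate that the pipeline's machinery
behaves as the formulas dictate (agreement drops with boundary
perturbation; median ICC is non-increasing in perturbation amplitude;
shape features are the least reproducible class under boundary jitter;
the semi-automatic methods agree with each other at least as well as with
the manual stand-in; planted class effects are recovered by the selector
and the classifiers at the expected rates; permuted labels give chance
performance). They do not certify behaviour on real PET. One real-data
direction is known **not** to reproduce here: on real cohorts the wavelet
LLL sub-band is the most reproducible and the high-pass bands the least,
whereas on these phantoms the ordering inverts — phantom high-pass content
is statistically homogeneous across the lesion, so mask jitter barely
moves its statistics while between-subject texture amplitudes give it a
strong subject signature; real high-pass content is patient-independent
reconstruction noise. Emulating that would require modelling the
reconstruction itself, which is out of scope. The corresponding acceptance
test asserts the real-data direction and is expected to fail on phantoms;
it is kept deliberately as an honest marker of this limitation.

## Problem sizes

The test suite exercises 12-subject cohorts (7 low / 5 high) for the
imaging-heavy fixtures, 3 jitter replicates at 1/2/4 mm for the
reproducibility patterns, 50-seed tabular simulations (n = 78, 200 noise
features) for selector recovery, 30×5 CV for the permutation null, and
500 simulations per type-I calibration check. `scripts/acceptance.py`
runs the full default cohort: 78 subjects, three segmentations each,
3 × 1781 features, 30×5×6 CV, 1000-resample bootstrap. All sizes are
package defaults chosen to keep a complete run comfortably interactive.
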