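# Methods

This note documents the models, parameter choices and numerical
conventions behind `mritil`, and what the synthetic-data tests do and do
not establish.

## Pipeline overview

Per case: bias-field correction → phase standardization (pre / early /
late) → fuzzy c-means parenchyma segmentation → intensity normalization by
pre-contrast parenchyma → 1-mm isotropic resampling → 2-cm peritumoral
shell → PE/SER kinetic maps → 17 features. Cohort level: univariate
correlation with BH-FDR control; LASSO stability selection + OLS refit of
a TIL signature; composite model with the cytolytic score; three-category
classification (ROC, Youden, DeLong); Kaplan-Meier / log-rank survival
stratification in the TNBC subgroup.

## Phantom model

A phantom is an ellipsoidal breast (45% of the grid extent per axis)
containing fat, a central fibroglandular region, and a lobulated
ellipsoidal tumor. Tissue kinetics are parameterized directly by
pre-contrast intensity, PE and SER; the early and late volumes are
constructed by inverting the PE/SER definitions, so a noise-free,
bias-free phantom reproduces the configured values at machine precision —
that is the identity the kinetic-map tests exploit.

Defaults (non-fat-saturated T1 convention): fat 1000 / PE 0.05 / SER 0.6;
parenchyma 400 / PE 0.4 / SER 0.8; tumor 600 / PE 1.2 / SER 1.3. The
fibroglandular region is a thresholded smoothed-noise field confined to
the inner 75% of the breast (so hole-filling recovers it inside the
fat-driven breast mask), with a quantile threshold targeting a 25%
parenchyma fraction. The bias field is the exponential of a random
second-order polynomial (amplitude 0.2 by default, zero-mean log over the
breast, normalized to mean 1), shared by all three phases as a
receive-coil field would be. Noise is additive Gaussian with SD expressed
as a fraction of parenchyma pre-contrast intensity (default 2%).

What the phantom does *not* emulate: pharmacokinetic (Tofts-type) uptake
curves, anatomically realistic breast shapes, inter-phase motion, Rician
noise, chest wall or skin. A green phantom test therefore establishes the
numerical correctness of the operators, not robustness to anatomy.

## Harmonization

**Bias correction.** A desk-scale surrogate for N4: a second-order 3-D
polynomial is fitted to log-intensities inside the breast mask and its
exponential (normalized to mean 1 over the mask) divided out. The fit is
iteratively reweighted (Tukey biweight, c = 4.685·MAD, 10 iterations),
*initialized from a constant median model*: this makes the dominant tissue
(fat) drive the fit and down-weights the darker fibroglandular center from
the start. An unweighted initialization provably fails here — a central
dark blob is itself well approximated by a quadratic, so the field absorbs
anatomy and correction worsens the volume. On default phantoms the robust
fit reduces RMS deviation from the unbiased truth by ~87% with noise and
by >99.99% noise-free.

**Phase standardization.** Early phase: the post-contrast scan inside the
[1, 4] min admissibility window nearest 2.5 min; late: the scan after
5 min nearest 7.5 min; ties break toward the earlier scan. The targets and
window are configuration.

**Normalization.** All phases are divided by the mean of pre-contrast
parenchyma voxels whose intensities lie in the closed [P25, P75] band
(linear-interpolation percentiles). This makes every downstream feature
invariant to global intensity scaling.

**Resampling.** Trilinear for intensities, nearest-neighbor for masks
(re-binarized at 0.5), `grid_mode` resampling with edge replication so
constant volumes stay constant; already-isotropic inputs are passed
through unchanged. Normalization precedes resampling; the order is a fixed
convention, as is applying the pre-contrast bias field to all phases.

## Segmentation

Breast: largest connected component above the Otsu threshold of the
pre-contrast volume, holes filled. Parenchyma: two-cluster fuzzy c-means
(fuzziness m = 2, tolerance 1e-5 on centroid movement, ≤ 200 iterations,
k-means++-style seeded initialization) on intensities inside the breast
minus the tumor; the darker-centroid cluster is parenchyma (brighter under
`fat_sat=True`). Shell: exact Euclidean distance transform honoring voxel
spacing; default 20 mm, restricted to parenchyma voxels (configurable to
all breast tissue). Tumor masks are inputs (phantom ground truth), not a
segmentation product.

## Features

GLCM conventions (unstated in the source literature, fixed here): SER
clipped to [0, 3] and uniformly quantized to 32 levels; a single symmetric
matrix pooled over the 13 unique unit-distance 3-D offsets, restricted to
tumor-internal pairs, normalized to sum 1; Haralick correlation, cluster
shade, energy and entropy (base-2); correlation of a constant map is
reported as 0. Surface area uses marching cubes on a lightly smoothed
(σ = 1) mask — meshing the raw binary mask keeps the voxel staircase and
overestimates a sphere's area by ~8%, which would bias sphericity. Margin
sharpness is the absolute directional derivative of the early-phase volume
along the outward surface normal (from the smoothed signed distance) at
boundary voxels — a monotone proxy for boundary sharpness rather than the
sigmoid-fit estimate used historically. All volume/fraction thresholds
(SER > 1.0/1.5, PE > 0.2/0.6) are strict inequalities. Voxels whose PE or
SER denominator magnitude is ≤ 1e-6 are excluded via the validity mask.

## Synthetic cohorts

Features are affine transforms of independent standard-normal latents at
plausible raw scales (the field reports no reference distributions, so
scales are free parameters). The TIL percentage is a clipped linear
function of the five designated standardized features using the fixed
signature coefficients (4.4, −3.14, −2.0, −2.62, −0.72) plus Gaussian
noise, clipped to [0, 90]. Log cytolytic activity follows a Gaussian
copula on the standardized noisy TIL latent with target correlation 0.51;
GZMA/PRF1 are log-normal with their geometric mean equal to the cytolytic
latent, so the score is exactly recoverable. Mutation counts are
Poisson-log-normal, weakly coupled (0.13). Recurrence times are
exponential with administrative censoring at 60 months; within the
TNBC-like (HR−/HER2−) subgroup, the no/minimal-TIL group's hazard is the
baseline (0.02/month) times the configured hazard ratio (default 2).

**Calibration of intercept and noise.** The generator must satisfy two of
its own contracts: (i) regressing generated TILs on the generating
features recovers the true weights within 3 SE at n ≥ 300, and (ii) the
full selection pipeline can identify the exact support at n = 500. These
bound the free parameters from two sides: clipping at 0 must be rare
(attenuation bias < 1 SE ⇒ intercept ≥ ~2.4 latent SDs) while the weakest
weight (0.72) must sit well above its standard error (noise SD ≤ ~2 at
n = 500). The defaults — intercept 16, noise SD 2 — satisfy both (clipped
fraction < 1%, weakest weight ≈ 8 SE). Consequences worth knowing: the
TIL distribution is approximately Gaussian around 16% rather than
right-skewed around 5% as in real cohorts, and the high category (> 40%)
is essentially absent, so three-category analyses exercise whichever pairs
exist. Weight-recovery tests compare *raw-scale* coefficients
(w/σ_feature): z-scale comparisons are confounded by the sample-SD jitter
of standardization (±3% at n = 500, larger than the OLS SE for the big
weights), which cancels exactly on the raw scale.

A green cohort test establishes that the statistical machinery recovers a
correctly specified linear world; it says nothing about feature
collinearity (latents are independent), non-linear TIL dependence, batch
effects, or real TIL distribution shape.

## Signature modeling

Standardization uses the n−1 SD convention. `lasso_select` reshuffles the
fold assignment per repeat from a seeded stream, picks the penalty per
repeat on a 50-point logarithmic grid down from the null-model alpha, and
counts a feature as selected when its full-data path coefficient at the
chosen penalty exceeds 1e-10 in magnitude (coordinate descent leaves
O(1e-16) residue exactly at the grid top). Data are centered per fold so
the path corresponds to an intercept-fitted LASSO.

Penalty rule: the library default is the CV-minimum MSE; the
one-standard-error rule is available via `one_se=True` and is what the
analysis drivers use. The reason is structural: with repeated CV on a
fixed dataset, a chance-correlated null feature that enters at the CV-min
penalty enters at *every* repeat — frequency thresholding cannot remove
it, and empirically most datasets (n = 500, p = 17) carry at least one
such stable false positive. The one-SE penalty removes them while keeping
all five true weights at the calibrated SNR. The final model is an OLS
refit on the selected columns (standard LASSO-refit practice; the
published coefficients are consistent with an unpenalized refit). The
composite model z-scores the cytolytic score before combination.

The published five-feature signature and the composite model are shipped
as fixed `SignatureModel` objects encoding the printed coefficients and
intercepts; they apply to z-scored inputs, and when training-cohort
standardization parameters are unavailable the applied cohort's own
means/SDs are used (recorded in model provenance).

The redundancy filter groups features whose pairwise ICC(2,1) on the
reference (manual-mask) table exceeds 0.85 — greedy single linkage in
column order — and keeps, per group, the feature with the highest
manual-vs-automatic ICC. "Linear ICC" is read as ICC(2,1) absolute
agreement; this is the one genuinely ambiguous term in the source
description.

## Evaluation statistics

ROC curves enumerate all empirical thresholds (score ≥ threshold =
positive); AUC is the trapezoidal integral and equals the tie-corrected
Mann-Whitney U/(n₁n₀) identically (a cross-implementation test asserts
this). The Youden threshold maximizes sensitivity + specificity − 1 with
ties broken toward the higher threshold (higher specificity); accuracy at
that threshold is unweighted. The DeLong test uses midrank placement
values, a normal two-sided p, no continuity correction; equal scores
return p = 1. Mann-Whitney is exact by enumeration for n₁+n₂ ≤ 12 without
ties, tie-corrected normal otherwise. ICC is ICC(2,1) (two-way random,
absolute agreement, single rater) from ANOVA mean squares. Kaplan-Meier
and the two-group log-rank test delegate to lifelines (events precede
censorings at tied times); Harrell's C counts pairs whose shorter observed
time is an event, with risk ties scoring 0.5.

## Known limitations

* N4, ComBat, motion correction, manual segmentation review, the
  110-feature superset and multivariate Cox modeling are out of scope.
* The bias surrogate assumes log-polynomial shading of order 2; stronger
  or higher-frequency coil patterns would leak into the field estimate.
* The survival power property sits at the edge of its 80% target at the
  committed seeds (39/50 replicates significant): the calibration that
  makes signature recovery identifiable leaves only ~18% of cases in the
  no/minimal group, costing log-rank power (the true-group ceiling is
  43/50), and prediction/truth group mismatch near the 10% cutpoint costs
  the rest. The two desk-scale requirements — identifiable weights and a
  well-populated low-TIL group — pull the single free intercept in
  opposite directions under a linear-Gaussian TIL model with the fixed
  published weights; the parameters were not re-tuned after measurement.
* FCM assumes a bimodal breast intensity histogram; fat-suppressed
  acquisitions need the `fat_sat` flag, and three-compartment breasts
  (e.g. marked biopsy artifacts) are not modeled.
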