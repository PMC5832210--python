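# Methods

This note documents the models, conventions and design choices behind
`nodal_petrad`, in the order data flows through the pipeline.

## Synthetic study conditions

The generator emulates a node-positive NSCLC FDG-PET cohort at the
development scanner's voxel spacing (4.0728 × 4.0728 × 3 mm) so the
extraction, pre-selection and modeling stages can be exercised against
known ground truth.

**Phantoms.** Each patient is a 44 × 44 × 36 voxel grid holding one
primary-tumor blob (radius drawn uniformly in 3.5–6.5 voxels) and 1–5
lymph-node blobs. Blobs are random axis-aligned ellipsoids (axis ratio
≤ 2) so shape features vary; a one-voxel moat keeps all structures
pairwise disjoint and 26-connected, and placement retries are bounded
(explicit error on an overfull grid). Node radii are lognormal (median
3.5 voxels, σ = 0.7): real nodal volumes span roughly two orders of
magnitude, and that size dominance is what makes the merged-node
structure resemble its largest node — the mechanism behind the
surrogacy stage. Uptake inside a blob is the blob mean times a
correlated lognormal texture field (Gaussian-filtered white noise of
correlation length 1 voxel, exponentiated, normalized to mean 1), with
coefficient of variation 0.2 by default; the field is strictly
positive and its heterogeneity is tunable, which is what the texture
families need. Between-patient uptake spread is lognormal with σ = 0.5
(printed SUV ranges in real cohorts span ~×30). Every patient draws
from an RNG stream keyed by (master seed, cohort, patient index), so
cohorts are bit-reproducible independent of generation order.

**Replicate segmentations.** Test-retest and inter-observer
delineations are emulated by `perturb_segmentation`: the signed
Euclidean distance to the mask contour is perturbed by a smooth
unit-variance noise field scaled by a magnitude in voxels and
re-thresholded at zero. Magnitude 0 is the identity; an empty result
raises. Default magnitudes (0.4 retest, 0.7 observer) are calibration
knobs, not estimates of any scanner's true variability — no replicate
acquisition details exist to estimate them from.

**Outcomes.** Survival times follow a Weibull proportional-hazards
model (shape 1.2, scale 24 months, median OS ≈ 18 months at zero
linear predictor) with log-hazard linear in the z-scored ground-truth
features. Censoring is administrative: a single cutoff at the
empirical (1 − rate) quantile of the drawn event times, independent of
covariates, hitting the target rate exactly up to rounding. The
default drivers put +0.50/SD on merged-node mean SUV, +0.35/SD on
merged-node GLCM entropy, and −0.30/SD on tumor GLRLM short-run
emphasis, so each model pool contains recoverable signal and the
node-vs-tumor asymmetry of the motivating study is reproduced
qualitatively.

**What the generator does not emulate** — and hence what passing tests
do *not* show about real data: PET point-spread/partial-volume blur,
respiratory motion, reconstruction artifacts, inter-scanner
differences, correlated tumor/node biology beyond shared patient-level
uptake, and informative censoring. Conclusions about the real cohort's
effect sizes cannot be read off the synthetic study.

## Feature extraction

**Discretization.** SUVs are binned at fixed width W = 0.5 SUV:
`I_D(x) = ceil(I(x)/W) − min_ROI ceil(I(x)/W) + 1`, so labels start at
1 and Ng is the maximum label. The same discretization feeds the
texture matrices and the first-order entropy/uniformity (one
discretization contract). Plain IEEE `ceil` is used; values lying
exactly on a bin boundary follow IEEE division semantics.

**Texture matrices.** Neighbors are the 26-connected voxels; the 13
unique offsets modulo sign, at distance one voxel, define the GLCM and
GLRLM directions. Each directional GLCM is symmetrized and normalized
to sum 1 before averaging; directions with no in-ROI pair are excluded
from the average. GLRLM counts maximal collinear runs confined to the
ROI, averaged over the 13 directions. GLSZM counts 26-connected
equal-level zones (directionless). All three equal brute-force
pair/run/zone enumeration entrywise on random small volumes (tested).

**Family rosters.** The feature count is fixed at 118 =
16 + 13 + 45 + 22 + 11 + 11:

- first-order (prefix `stats_`): min, max, range, mean, median, SD,
  variance, skewness, kurtosis, energy, entropy, uniformity, mean
  absolute deviation, RMS, SUV-peak, coefficient of variation.
  SUV-peak is the ROI-restricted mean over the 3×3×3 voxel
  neighborhood (~1.5 cc at development spacing) centered on the
  hottest voxel — deterministic on anisotropic grids.
- shape (`shape_`): volume (cc), surface area (mm², marching-cubes
  triangulation of the binary mask at iso-level 0.5 with physical
  spacing), surface/volume (cm⁻¹), sphericity, compactness-1,
  compactness-2, spherical disproportion, maximum 3D diameter, maximum
  in-plane diameter for each orthogonal plane, elongation, flatness.
  Diameters are the largest pairwise distances between voxel *corners*
  (full physical extent; a cube of side a measures a√3), pruned by
  convex hull. Elongation/flatness are √(λ2/λ1), √(λ3/λ1) of the
  voxel-cloud principal axes; both are defined as 1 for a single voxel.
- IVH (`ivh_`): volume fractions Vx at x = 10…90% of the ROI intensity
  range (9); intensity thresholds Ix of the hottest x% volume,
  x = 10…90 (9); differences Vx − V(100−x) and Ix − I(100−x) for
  x = 10…40 (8); absolute-threshold volume fractions and residual
  volumes in cc at SUV 1…9 (18); area under the range-normalized IVH
  (1), which collapses to (mean − min)/range and is 1 for a constant
  ROI.
- GLCM (`glcm_`, 22): autocorrelation, cluster prominence/shade/
  tendency, contrast, correlation, difference entropy, dissimilarity,
  energy, entropy, homogeneity-1/-2, IMC1, IMC2, IDMN, IDN, inverse
  variance, maximum probability, sum average/entropy/variance,
  variance. Logarithms are base 2. On a degenerate single-level matrix
  the correlation-type features return 0 (correlation, IMC1, IMC2)
  rather than 0/0.
- GLRLM (`glrlm_`, 11): SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE,
  SRHGE, LRLGE, LRHGE; GLSZM (`glszm_`, 11): the zone-based analogues
  (SAE, LAE, GLN, ZSN, ZP, LGZE, HGZE, SALGE, SAHGE, LALGE, LAHGE).

Where the first-order and IVH rosters admit alternatives, the lists
above are frozen so the totals and the model-relevant names
(`glrlm_sre`, `glrlm_gln`, `glrlm_srhge`, `glcm_entropy`,
`stats_uniformity`, `shape_volume_cc`, `shape_surface_to_volume_ratio`)
are stable.

**Nodal structures.** All features of a patient's nodes are computed on
the voxelwise union `LN_merged` directly (one texture matrix over the
whole union, spatially separate components and all); the alternative —
aggregating per node — is deliberately not implemented, matching the
merged-structure convention. Ties in largest/most-active node
selection break by input order.

## Pre-selection

The ICC is the two-way random-effects, absolute-agreement,
single-measurement form ICC(2,1), from the standard ANOVA mean
squares; it is the stricter of the common variants and the usual
radiomics choice. Robustness requires ICC > cutoff (default 0.85) in
*every* provided context; zero-variance features are dropped (ICC
undefined) rather than erred on. Limits of agreement are
mean ± 1.96·SD of the pairwise percent differences
d = 100(A − B)/((A + B)/2); surrogacy requires the whole interval
inside ±10% — the endpoint-containment reading — against *both*
LN_volume and LN_max (conjunctive reading of "largest or most
active"); the disjunctive variant is exposed as `mode="either"`.

## Survival modeling

**LASSO-Cox.** Features are standardized internally (L1 selection is
scale-sensitive) and back-transformed for reporting. The path is
solved by coordinate descent (scikit-survival's Coxnet, l1_ratio = 1);
the penalty is chosen at the maximum of the Verweij–Van Houwelingen
cross-validated log partial likelihood (full-data logPL at the
training-fold coefficients minus training logPL, summed over 10
event-stratified folds) — the CV-deviance minimum, not the 1-SE rule.
Fold assignment is stratified by event status under a recorded seed.
An empty selection is a returned result, not an error.

**Refit and reporting.** Selected features are refit unpenalized
(lifelines) on the whole cohort; hazard ratios, Wald p-values and 95%
CIs come from that fit. Merged-node volume enters models on its
natural-log scale (its univariable effect is log-shaped). AIC =
2k − 2 logPL with the Breslow partial likelihood evaluated at the
fitted coefficients; model comparison reports ascending AIC.

**Concordance.** Harrell's C counts pairs (i, j) with t_i < t_j and
d_i = 1; tied risks score 0.5. The 95% CI uses the delete-one-subject
jackknife variance of the pair-count U-statistic, computed exactly in
O(n²) from per-subject pair sums — numerically the standard asymptotic
variance for this statistic; a subject-resampling bootstrap is the
config alternative. External validation freezes the development
coefficients and scores the validation cohort.

**Diagnostics.** Log-linearity: a univariable Cox fit on a restricted
(natural) cubic spline basis (4 quantile knots, linear beyond the
boundary knots, basis orthonormalized for conditioning, light ridge
ladder 1e-6 → 0.1) is compared to the linear fit by a likelihood-ratio
test on the nonlinear block; verdict "log-linear" at p ≥ 0.05,
"non-linear" otherwise, with a log-transform recommendation when the
log scale restores linearity, and "indeterminate" when the covariate
is too discrete to support knots. Proportional hazards: scaled
Schoenfeld residuals and the standard residual-vs-log(time)
correlation test (lifelines), emitted as plot-data CSVs.

**Clinical covariates** (age, gender, stage, N stage, LN-station
count, histology, RT dose, chemotherapy) are screened univariably with
first-level reference coding but are *not* entered into models 1–3 —
the models are imaging-only by design.

## Numerical and sizing choices

- Default study size: 262 development + 50 validation patients; the
  full pipeline (phantoms, ~1,800 feature extractions, three CV-LASSO
  models, diagnostics, reports) runs in ~1.5 minutes on one CPU.
- Monte-Carlo contracts in the test suite use enough replicates to
  keep the binomial error well inside the asserted margins (e.g. 300
  replicates for the planted-feature selection/coverage check).
- Texture matrices operate on the padded bounding box of the mask;
  GLCM bin counting is vectorized per direction; GLRLM run lengths are
  found by iterative shift-propagation; GLSZM uses 3D connected-
  component labeling per grey level.
- Degenerate inputs are contracts, not crashes: empty masks, constant
  features, single-voxel ROIs, all-censored cohorts and empty LASSO
  selections all have defined behavior (error or documented value).

## Known limitations

- The synthetic surrogacy stage retains few features (~2–17 depending
  on cohort draw) because independent per-node texture sampling
  disagrees more than real within-patient node biology; the retained
  counts are emulation outcomes, not targets.
- Post-selection Wald CIs are reported without selective-inference
  correction (measured coverage ~93–95% for a strong planted effect).
- No image resampling/harmonization between cohorts with different
  voxel sizes; features are computed on the native grid.
- 2D (per-slice) texture variants, wavelet/filtered-image features and
  CT-based features are out of scope.
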