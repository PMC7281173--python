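# Methods

This document records the model, the assumptions behind it, the default
parameter choices, and the known limitations of the analysis. All numeric
defaults below are frozen design decisions made before the test suite was
run; they are the study conditions, not tunables.

## 1. Problem setting

The analysis asks whether texture (heterogeneity) features computed from a
pelvic [18F]FDG-PET volume predict bone-marrow involvement and marrow
infiltration burden in a lymphoma cohort, and whether they add information
beyond plain SUV intensity metrics. Because no patient imaging can ship
with the code, the entire study runs on a synthetic phantom cohort with
known ground truth; every downstream component (segmentation, radiomics,
harmonization, signature, classification) is the same code that would run
on real NIfTI volumes.

## 2. Synthetic cohort

Each patient record carries: involvement status, relative marrow
infiltration REL (% of nucleated cells), marrow cellularity (%), absolute
infiltration ABS = cellularity x REL / 100, WBC, LDH, Ki-67, and a scanner
identifier.

Marginal distributions are truncated normals on [0, 100] (labs on wider
supports), with class-conditional parameters so that laboratory values are
mildly informative for involvement. Involvement prevalence defaults to
0.691.

Two fitting helpers construct these distributions:

- `TruncatedNormal.from_moments(mean, sd)` finds the truncated normal
  whose first two moments are nearest the targets in a least-squares
  sense. For some (mean, sd) targets no truncated normal on [0, 100]
  attains them exactly (the family's SD is bounded given the mean); the
  nearest member is used and the achieved moments are exposed as
  `dist.mean` / `dist.sd`. E.g. the REL target (33.0, 29.1) resolves to
  achieved moments (34.0, 26.1). Calibration tests compare samples to the
  achieved moments, not the infeasible targets.
- `TruncatedNormal.from_tail(threshold, tail_prob, sd)` places the
  distribution so that P(X >= threshold) matches a requested exceedance
  probability (used for Ki-67, where the meaningful constraint is the
  fraction above the 30% cut-off).

`build_margin_cohort()` is a separate deterministic construction that
reproduces a fixed set of reference endpoint margins exactly (n = 97;
positives 67 / 46 / 41 / 43 / 35; Ki-67-high 33 of 67). It exists to pin
the stratification and rounding logic (half-up to one decimal) against
hand-checkable counts and is not sampled.

## 3. Phantom volumes

Each patient's PET volume is a 64 x 64 x 32 grid at 5.5 x 5.5 x 3.3 mm
spacing (35 x 35 x 10.5 cm field of view):

1. **Pelvis mask.** Two mirrored ellipsoid shells ("iliac wings",
   ~22,000 voxels, ~17% of the grid) define the marrow search region.
   The mask is shared by all patients.
2. **Marrow texture.** A stationary Gaussian random field (white noise
   smoothed with an anisotropic Gaussian kernel, renormalized to its
   empirical SD) modulates a constant marrow mean. Infiltration moves
   the field parameters: the default preset shifts the marrow mean by
   0.008 SUV per REL% and interpolates correlation length and amplitude
   between an uninvolved (6 mm, SD 0.25) and involved (12 mm, SD 0.30)
   state with REL.
3. **Focal lesions.** Poisson-distributed spheres (rate 0.05 per REL%,
   radius 8 mm, multiplicative boost 1.5) model focal uptake.
4. **Scanner effects.** Four scanner profiles (S1-S4) apply a PSF blur
   (FWHM 4 / 5.5 / 7 / 8 mm), a global gain (0.9-1.1), a small additive
   offset and a noise-amplitude factor. These are the batch effects that
   ComBat later removes.
5. Background tissue sits at SUV 0.8; Gaussian noise (sigma 0.12 before
   the scanner factor) is added and the volume clipped at 0.

Per-patient seeds derive from one master seed through `numpy
SeedSequence` (masked below 2^31), so cohorts are exactly reproducible.

### The `texture_only` preset

For validation experiments that must isolate texture information, the
`texture_only` preset removes every intensity pathway: no mean shift, no
lesions, equal field SD (0.30) in both classes. The two classes differ
only in spatial correlation length, 8 mm (uninvolved) vs 14 mm
(involved). Both lengths are deliberately larger than twice the largest
scanner PSF sigma (3.4 mm) so that scanner blur attenuates the two
classes' field amplitude nearly equally; with shorter lengths the blur
itself converts the correlation difference into an SUV-amplitude
difference (a longer-correlation field also has fewer independent voxels
and hence a lower expected maximum), which would leak class signal into
SUVmax and defeat the preset's purpose. This choice is a design
consequence of the preset's stated goal, fixed before any classifier was
trained.

## 4. Segmentation and radiomics

- **MTV.** The metabolic tumor volume is every search-region voxel with
  SUV >= 0.41 x SUVmax, where SUVmax is the single global maximum over
  the search region. Ties at the threshold are included; no
  connected-component filtering is applied.
- **SUV metrics.** SUVmax, SUVmean over the MTV, and SUVpeak = mean over
  the voxels whose centers lie within a 1 cm^3 sphere (radius 6.2035 mm)
  centered on the hottest voxel, clipped at the volume boundary.
- **Discretization.** Default fixed-bin-number with Ng = 25 levels:
  `level = min(Ng, floor(Ng (x - min)/(max - min)) + 1)`, constant
  regions map to level 1. A fixed-bin-width mode
  (`floor((x - min)/w) + 1`) is provided as an alternative; bin-number
  discretization is amplitude-invariant, which matters when texture must
  be compared across gain-varying scanners.
- **GLCM.** The 13 unique Chebyshev-distance-1 3D direction offsets
  (lexicographically positive) each yield a symmetric, normalized
  co-occurrence matrix; 16 Haralick features are computed per direction
  and averaged (a merged-matrix mode exists as an option). Degenerate
  conventions: 0 log 0 = 0; correlation = 1 when a marginal SD vanishes;
  IMC1 = 0 when max(HX, HY) = 0; IMC2 clamped at 0 before the square
  root. Natural logarithms by default. A constant region therefore has
  ASM = homogeneity = IDM = max-probability = 1 and entropy = contrast =
  shade = IMC2 = 0 exactly.

The feature vector per patient is 3 SUV metrics + 16 texture features =
19 values (plus MTV in ml, carried along for reporting).

## 5. ComBat harmonization

Parametric empirical-Bayes ComBat without biological covariates,
operating on the 19-feature table with scanner as batch:

- standardize each feature against the batch-size-weighted grand mean
  and the pooled variance of residuals around batch means (divisor N);
- estimate per-batch location gamma-hat and scale delta2-hat on the
  standardized data;
- moment-match a normal prior for gamma (gamma-bar, tau^2 across
  features) and an inverse-gamma prior for delta^2
  (lambda = (2 s^2 + m^2)/s^2, theta = (m s^2 + m^3)/s^2);
- iterate the coupled posterior updates to convergence (tolerance 1e-6,
  cap 100 iterations);
- adjust y* = sd_pooled (z - gamma*)/delta* + grand mean.

Residual batch gaps are assessed in units of each harmonized feature's
own standard deviation — the only unit in which "agree within 0.1 SD" is
well defined when batches carry scale effects. Laboratory values are not
scanner-derived and are never harmonized. Singleton batches, single-batch
tables, zero-variance features and unseen batch labels are rejected.

## 6. Radiomic signature

PCA on the correlation matrix of the 19 harmonized features: features are
z-scored (ddof = 1), the correlation matrix eigendecomposed, and every
component with eigenvalue > 1 retained (Kaiser criterion). Loading signs
are fixed by making the largest-magnitude entry positive. Scores are the
projections of the standardized features on the retained loadings. The
default pipeline fits the signature on the full cohort (matching the
common radiomics workflow); a stricter `pca_fit: train_only` option
refits the signature inside each training split.

## 7. Classification

Six endpoints: involvement (yes/no), REL > 5%, REL > 10%, ABS > 5%,
ABS > 10% (strict inequalities), and Ki-67 >= 30% among involved patients
only. Three feature sets: `suv` (3 SUV metrics), `signature` (retained
PC scores), `signature+labs` (scores + WBC + LDH; not offered for the
involved-only Ki-67 endpoint, where labs were defined class-conditionally
on involvement).

Each endpoint x feature-set cell is evaluated with 5 repetitions of a
stratified 70/30 split (per-class counts rounded half-up). By default the
split is fixed across repetitions and only the MLP weight initialization
is reseeded (seed = master + repetition); `resample_split` redraws the
split too. Features are standardized on the training split. The
classifier is a scikit-learn `MLPClassifier`: one hidden layer of 3 tanh
units, lbfgs solver, fixed random state. Reported per run: training and
test accuracy (%), and the held-out AUC computed by the rank-sum
(Mann-Whitney) formula with midranks for ties — identical to exhaustive
pair enumeration.

## 8. Problem sizes and runtimes

Chosen to keep the full study tractable on one CPU core:

| quantity | value |
|---|---|
| phantom grid | 64 x 64 x 32 voxels |
| default cohort | n = 97 |
| validation (texture) cohort | n = 200 |
| per-patient simulate + extract | ~0.1 s |
| full pipeline (`marrowpet run`) | ~10 s |
| test suite | ~30 s |
| acceptance script | ~10 s |

## 9. Limitations

- The phantom is a statistical texture model, not anatomy: no organs, no
  bladder uptake, no attenuation or reconstruction physics. Scanner
  effects are a parametric caricature (blur + affine intensity + noise).
- The Gaussian random field is stationary within the marrow mask; real
  infiltration is spatially heterogeneous.
- ComBat is run without biological covariates; with strongly
  scanner-confounded cohorts this removes biology along with batch.
- The default signature is fit on the full cohort before splitting, so
  component definitions see the test patients (scores, not labels); the
  `train_only` mode quantifies the difference.
- n = 97 with repeated 70/30 splits gives wide AUC dispersion across
  runs; medians over 5 runs are reported for comparability, not as
  confidence statements.
- Truncated-normal marginals cannot reach every (mean, SD) target on
  [0, 100]; the nearest-moment fit is documented above and exposed via
  the distribution objects.
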