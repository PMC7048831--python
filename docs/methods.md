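# Methods

This note documents the models, estimators and design choices behind
`gliomics`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Imaging model and data contracts

A case consists of four co-registered, skull-stripped, 1 mm isotropic MRI
volumes (T1, T1Gd, T2, FLAIR), a BraTS-convention segmentation (1 = NCR/NET
necrosis and non-enhancing tumor, 2 = ED edema, 4 = ET enhancing tumor) and
an optional brain mask; when no brain mask is supplied the nonzero support
of T1 is used, which is exact for skull-stripped inputs. Arrays are indexed
(x, y, z) with z inferior→superior, so the "z" viewpoint is the axial
projection. Sub-region masks are disjoint by construction and their union
is the whole tumor (WT); empty sub-regions are legal and propagate
degenerate flags rather than errors. Cases with a missing label for a
target are excluded from that target's modeling cohort.

## Roughness estimators

**PTPSA.** On a w×w patch, corner heights are sampled on the grid
0, s, 2s, …, m·s with m = ⌊(w−1)/s⌋; each cell contributes four triangles
joining adjacent corners to the center point at the mean corner height.
Because partial coverage (when w−1 is not a multiple of s) would make the
areas incomparable across scales, each A(s) is rescaled to a common planar
footprint; a flat or planar patch then yields exactly equal areas at all
scales and D = 2 exactly. D = 2 − slope of an unweighted least-squares fit
of log A(s) on log s over all configured steps (default {1, 2, 4, 8}),
clipped to [2, 3].

**mBm Hurst.** A separable 2D discrete wavelet transform (Daubechies-4,
periodization, J = 3 levels by default) gives per-level detail variances
V(j); H = (slope of log₂ V(j) on j − 2)/2, clipped to [0, 1]. White noise
drives the slope to 0 and is clipped at H = 0; constant patches (all detail
bands zero) return the upper clip with a degenerate flag. The estimator is
cross-checked in the tests against an independent variogram oracle
(E|I(x+h) − I(x)|² ∝ |h|^{2H}).

**Hölder exponent.** osc_r = max − min of intensity in the Chebyshev ball
of radius r (default radii {1, 2, 3, 4}); α = slope of log(osc_r + ε) on
log r with ε = 1e−6; locally constant neighborhoods return α = 2.0
(`alpha_cap`). All three estimators are invariant under adding a constant
to the intensities; mBm and HE are also invariant under positive scaling.

**Characterization maps.** Maps are computed slice-wise (axial) with a
17-voxel window centered on each in-ROI voxel; the volume is cropped to the
ROI bounding box with a half-window margin and reflect-padded at crop
edges, so out-of-ROI intensities influence in-ROI values only within the
window support. The HE map is computed with 3D min/max filters. By default
the three maps are derived once per case from FLAIR (the most
tumor-conspicuous sequence); a config switch computes them per sequence.
The window and scale parameters are conventions, not fitted values, and are
exposed in `FractalMapConfig`.

## Texture and shape catalogue

Intensities are min–max quantized to Ng = 32 equal-width levels inside the
ROI (affine-invariant by construction). Texture matrices are fully 3D:
symmetric GLCM merged over the 13 unit offsets at Chebyshev distance 1;
GLRLM merged over the same 13 directions; GLSZM with 26-connected zones;
NGTDM over the 26-neighborhood. Out-of-mask neighbors are excluded
everywhere; each family is verified against brute-force enumeration on
random 5³ ROIs. The 41-feature catalogue (GLCM 10, GLRLM 13, GLSZM 13,
NGTDM 5) uses the standard published formula for every named feature;
entropies are in bits. Zero-variance GLCMs set correlation and both
information measures of correlation to 0 with a degenerate flag.

Histogram statistics are population moments (kurtosis is not excess, i.e. a
Gaussian gives 3) plus histogram energy Σp² and entropy −Σp log₂p over 64
equal-width bins. Volumetric features are the 12 volume ratios of
WT/ED/ET/NCR against each other and the brain; a zero denominator yields 0
with a flag. Shape properties are measured with scikit-image regionprops on
the any-voxel projection along each axis; orientation is reported in
degrees in (−90, 90] from the first in-plane axis; axis lengths are
4·√(eigenvalue of the second central moments). The default catalogue is
516 columns; the per-sequence-maps variant is 744 (the map histogram block
is specific to the single-source variant, keeping the catalogue within its
documented size band).

## Prediction protocol

Stratified 75/25 partitions use largest-remainder per-class allocation, so
a 108-case cohort always splits 81/27 and per-class proportions are within
one case of the cohort's. Feature selection is recursive: a random forest
(150 trees, impurity importances, ties broken by name) ranks all features
once per outer fold; the ranking is truncated to each candidate size in
{2, 3, 5, 7, 9, 11, 13, 15} and each candidate set is scored by pooled
out-of-fold AUC from an inner leave-one-out loop of the boosted-tree
classifier. Inner AUC is pooled rather than fold-averaged because LOOCV
folds of size one admit no per-fold AUC. Ties in the inner AUC favor the
*larger* candidate size: cross-validated performance of these models
improves and stabilizes with more selected features, and small tied sets
proved to be the unstable ones. Training sets below five times the largest
candidate size trigger a warning, not an error.

The outer leave-one-out loop scores each held-out case with a model
selected and trained without it; cross-validated AUC/sensitivity/
specificity come from the pooled out-of-fold probabilities. The final
feature set is the inner-loop maximizer over outer folds; distinct tied
maximizers are intersected, and an intersection smaller than the smallest
admissible candidate size (2) falls back to the smallest tied set with a
flag. The final model is retrained on the full training partition and
evaluated on the untouched test partition. Sensitivity/specificity use a
0.5 probability threshold with the aberrant state (mutated / methylated /
co-deleted) as the positive class.

Boosted-tree defaults: learning rate 0.3, depth 3, 50 rounds, L2 = 1,
L1 = 0, positive-class weight N_neg/N_pos, fixed seed. These are
conventions for small tabular problems (tens of cases, ≤ 15 features);
rounds beyond ~50 change nothing detectable at these sizes while the fully
nested protocol multiplies every per-fit cost by roughly n² × 8. All are
config-exposed. The three-class IDH/1p19q model replaces the binary AUC
with the Hand–Till M (mean of all pairwise one-vs-one AUCs) for inner
scoring and reporting.

The fractal ablation repeats the entire analysis after dropping every
feature whose source is a PTPSA/MBM/HE map (141 columns of the default
catalogue), on the same partitions (the repetition seeds derive from the
same master seed), so with/without comparisons are paired. The ANOVA used
to compare repetition metrics between variants mirrors the reporting
convention of this literature; with paired repetitions a paired test would
be more powerful, and both views are available from the per-repetition CSV.

## Survival layer

Median-split stratification standardizes the covariate, splits at the
median with ties to the lower group, fits product-limit curves per group
and reports the unweighted two-group log-rank χ² and p (lifelines). The Cox
model is univariate on the standardized covariate, so the hazard ratio is
per standard deviation and scale-invariant; the likelihood-ratio test
compares 2(ℓ₁ − ℓ₀) to χ²₁. Null calibration (type-I error of the LR test
near 0.05) is verified over 500 simulated cohorts.

## Synthetic phantoms: what they emulate, and what they do not

Each phantom is a brain ellipsoid with nested spherical tumor compartments
(defaults: NCR 5, ET 9, ED 16 voxels on a 72³ grid — a 32 mm tumor, large
relative to the 17-voxel analysis window so that in-slice windows see
texture rather than region boundaries). Modalities are piecewise-constant
tissue means (loosely mimicking T1/T1Gd/T2/FLAIR contrasts), blurred with a
1-voxel Gaussian partial-volume kernel, plus unit-variance spectrally
synthesized fractional Brownian texture, multiplied by a per-case smooth
bias field (strength uniform on [0, 1.0], correlation length 0.3 × grid —
uncorrected scanner shading), plus white noise of SD 0.1.

The molecular class acts on the tumor texture's Hurst exponent: base
H = 0.5 shifted by ±effect_hurst/2 per class, with per-case jitter of
SD 0.03 (biological within-class variability), and optionally on the tumor
radii through `effect_volume`. The bias field is the designed mechanism
that separates the two feature families: log-log slope estimators
(PTPSA/mBm/HE) cancel smooth multiplicative gain, whereas min–max
quantization-dependent raw texture statistics absorb it as between-case
variability. The generator also ships an optional fine-scale spectral
matching mode (`increment_match_h`) that mixes each class field with a
rough filler so all classes share variance and lag-1 increment variance;
it is off by default — with total variance fixed, exact fine-scale matching
provably caps the class contrast available to *any* statistic, fractal
maps included — but is kept as a tested instrument for studying which
scales carry class information.

A second gain-like nuisance is available as an option
(`gamma_log_range`): a per-case smooth monotone remap of the brain
intensity range (a scanner-nonlinearity surrogate), rank-preserving and
therefore locally linear; it is off by default.

Survival times are exponential with rate baseline_rate·exp(β·z), where z is
the standardized per-case tumor Hurst (plus small jitter), independently
exponentially censored; z is recorded in the cohort table as `driver_z`.
The permutation calibration of feature-association screening uses this
driver covariate: parametric ANOVA p-values are markedly conservative for
heavy-tailed radiomic features at cohort sizes in the twenties, which is a
property of the F-test's normality assumption, not of the implementation;
the Gaussian driver isolates the procedure's own calibration.

What passing tests on phantoms do **not** show: anatomical realism (no
tissue anatomy, single centered tumor, spherical compartments), MR physics
(no Rician noise floor, no sequence-specific artifacts), segmentation
error (masks are exact by construction), or the label correlations of real
LGG cohorts (targets are drawn independently except for the IDH/1p19q
nesting in the reference table). Absolute AUC values on phantoms therefore
say nothing about clinical performance; they validate the pipeline's
mechanics, calibration and the relative value of the fractal block under a
known ground truth.

## Problem sizes and numerical choices

The validation suite runs the full nested protocol at reduced cohort sizes
chosen as the package's own desk-scale defaults: the strong-effect
ablation uses 32–36 cases with 10 paired repetitions, the null runs 24
cases with 8 repetitions, estimator recovery uses twenty 128² patches per
Hurst value, and the Cox null calibration 500 cohorts of 40. The reference
108-case label table reproduces the published class margins (IDH 85/23
with 27 co-deletions among mutants, 1p/19q 27/81, ATRX 43/65, TERT 46/62,
MGMT 91/14 with 3 unlabeled, assigned deterministically in case order with
the last three cases carrying the missing MGMT labels).

Numerical conventions: AUC is the normalized Mann–Whitney U with ties
counted ½ (verified against brute-force pair counting); random-forest ties
break by feature name; all stochastic stages draw named substreams from a
single master seed, making simulate → extract → model → survival exactly
reproducible; degenerate inputs (constant ROIs, empty sub-regions, zero
denominators) produce defined values with flags rather than NaNs, keeping
the design matrix rectangular.

## Known limitations

GLRLM/GLSZM zone and run statistics are themselves multi-scale, so the
"non-fractal" block is not scale-blind; the fractal ablation measures the
incremental value of explicit scaling-exponent maps, not of multi-scale
information per se. The mBm map uses a 3-level transform on 17² windows,
below the nominal decomposition-depth requirement of the standalone
estimator; it is a texture descriptor at map scale, and its pointwise
values are noisier than the patch-level estimator validated at 128². The
per-sequence catalogue variant approximates, but cannot exactly reproduce,
a published catalogue of around 680 features whose composition is not
fully specified; both variants are provided and the count is validated as
a band, not an equality.
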