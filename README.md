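# gliomics

Fractal and multi-resolution radiomics for molecular subtyping of diffuse
low-grade glioma (LGG), exercised end-to-end on synthetic 3D tumor phantoms.

Diffuse low-grade gliomas (WHO grade II–III) are classified by molecular
alterations — *IDH* mutation, 1p/19q co-deletion, *ATRX* and *TERT*
mutations, and MGMT promoter methylation — that normally require invasive
tissue sampling. This package implements a non-invasive alternative: it
predicts each alteration from multimodal MRI (T1, T1Gd, T2, FLAIR) of the
segmented tumor, with particular emphasis on **fractal and multi-resolution
fractal texture**, and provides a synthetic phantom generator with known
ground truth so that every stage of the pipeline can be validated without
patient data.

## The method

**Texture characterization.** Three pointwise roughness maps are computed
over the whole tumor (WT = necrosis ∪ enhancing tumor ∪ edema, BraTS labels
{1, 4, 2}):

* *PTPSA* — piecewise triangular-prism surface area. Local intensity is a
  height field; the triangulated surface area A(s) over cells of size s
  scales as A(s) ∝ s^(2−D), giving the fractal dimension
  D = 2 − slope[log A(s) / log s] ∈ [2, 3], with D ≈ 3 − H for fractional
  Brownian surfaces.
* *mBm* — multifractional Brownian motion Hurst map. Wavelet detail
  variances of 2D fBm scale as V(j) ∝ 2^{j(2H+2)}; the local Hurst exponent
  is H = (slope[log₂ V(j) / j] − 2)/2 ∈ [0, 1] (small H = rough).
* *HE* — pointwise Hölder exponent. The oscillation of intensity in a ball
  of radius r scales as r^α; α is the slope of log(osc + ε) on log r.

**Feature catalogue.** Per case, 516 named features
(`<source>.<region>.<family>.<feature>`): 41 texture features (GLCM 10,
GLRLM 13, GLSZM 13, NGTDM 5; 32 gray levels, 3D matrices merged over the 13
unit directions) on WT for T1Gd/T2/FLAIR and for the three maps; 6 histogram
statistics (mean, variance, skewness, kurtosis, energy, entropy) per
sub-region and per map; 12 volumetric ratios; and 168 projection shape
properties (area, bounding box, centroid, perimeter, axis lengths,
eccentricity, orientation, solidity, extent for 4 regions × 3 viewpoints).

**Prediction protocol.** For each molecular target: repeated stratified
75/25 train/test partitions; within each training partition a nested
leave-one-out cross-validation — a random forest ranks features, candidate
subsets of size {2, 3, 5, 7, 9, 11, 13, 15} are scored by inner-LOOCV AUC of
an XGBoost classifier (additive tree ensemble ŷᵢ = Σₖ fₖ(xᵢ) with L1/L2
regularization and positive-class weighting), and the final feature set is
the inner-loop maximizer across outer folds (ties intersected). Test AUC,
sensitivity and specificity are reported as mean ± SD over repetitions, with
and without the fractal feature block. A three-class IDH/1p19q model uses
the Hand–Till multiclass AUC. The survival layer provides median-split
Kaplan–Meier curves with the log-rank test and univariate Cox hazard ratios
per standard deviation, assessed by the likelihood-ratio test.

**Phantoms.** Synthetic cases are nested-ellipsoid tumors (necrotic core,
enhancing shell, edema) inside a brain ellipsoid, rendered per modality as
tissue mean + unit-variance fractional Brownian texture + noise, blurred by
a partial-volume kernel, and shaded by a per-case smooth multiplicative
bias field. A molecular class acts on the texture's Hurst exponent (and
optionally on tumor volume), and survival times follow an exponential model
with a log-linear hazard in a designated driver covariate.

## Worked example

```python
import numpy as np
from gliomics import (PhantomSpec, SyntheticCohortSpec, generate_cohort,
                      assemble_cohort_features, run_repetitions)

cohort = generate_cohort(SyntheticCohortSpec(n_cases=32, effect_hurst=0.4, seed=11),
                         PhantomSpec())
X = assemble_cohort_features(cohort)          # 32 cases x 516 features
y = cohort.label_table.set_index("case_id")["IDH"]

for variant in ("with_fractal", "without_fractal"):
    res = run_repetitions(X, y, "IDH", variant, n_reps=10, master_seed=5)
    aucs = [r.test["auc"] for r in res]
    print(variant, round(np.mean(aucs), 3))
```

prints

```
with_fractal 0.912
without_fractal 0.85
```

i.e. on phantoms whose IDH class differs only in tumor texture roughness
(ΔH = 0.4), the full model predicts the class from held-out cases with mean
test AUC 0.91 over ten independent partitions, and removing the
PTPSA/mBm/HE-derived features drops the mean test AUC to 0.85 — the fractal
block carries predictive information that the remaining intensity, texture,
volumetric and shape features do not fully recover.

The same pipeline is available from the shell:

```
gliomics simulate --out cohort/ --n-cases 32 --effect-hurst 0.4 --seed 11
gliomics extract  --cohort-dir cohort/ --out features.csv
gliomics model    --features features.csv --cohort-csv cohort/cohort.csv \
                  --out results/ --target IDH --variant both --n-reps 10 --seed 5
gliomics survival --features features.csv --cohort-csv cohort/cohort.csv \
                  --feature-name MBM.WT.histogram.entropy --out survival.json
```

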