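# tumortex

Slice-wise CT texture analysis for predicting 2-year survival in pancreatic
ductal adenocarcinoma (PDAC), built as a reusable, tested Python library.

PDAC varies on contrast-enhanced CT from homogeneously isoattenuating
masses to heterogeneously hypovascular tumors, and that visual
heterogeneity plausibly reflects underlying histologic or genetic
differences that correlate with outcome. `tumortex` quantifies it: from a
3-D CT volume and an aligned binary tumor mask it extracts an ordered,
named vector of **255 intensity- and edge-based texture features** per
tumor, selects a compact discriminative subset with **fuzzy
minimum-redundancy maximum-relevance (fMRMR)** ranking plus forward
selection, and evaluates a **Gaussian naive-Bayes classifier** of 2-year
survival under leave-one-image-out and repeated stratified 3-fold
cross-validation, with selection nested inside every training fold.

Because the original 35-patient clinical cohort is not publicly deposited,
the package ships a synthetic-data module that emulates the study's
structure (20 short-term vs 15 long-term survivors, ellipsoidal tumors on
a pseudo-Hounsfield scale) with a tunable homogeneous-to-heterogeneous
texture continuum, so every stage is testable end to end.

## The feature vector

Features are computed per axial slice over the mask-restricted tumor
cross-section and averaged over slices:

| block | count | content |
|---|---|---|
| G1–G19 | 19 | gray-level co-occurrence matrix (GLCM, d=2, N=16, 4 directions): 14 Haralick features + inertia, cluster shade, cluster prominence, Renyi entropy (q=8), Tsallis entropy (r=2) |
| R1–R11 | 11 | run-length matrix features, 4-direction averaged |
| L1–L128 | 128 | local binary patterns: ULBP histogram (59), rotation-invariant ULBP (10), histogram statistics (21), LBP histogram-Fourier (38) |
| F1_1–F1_48 | 48 | SFTA: 16 Otsu-threshold binary images × (border box-counting fractal dimension, mean gray, size) |
| F2_1–F2_6 | 6 | differential box-counting FD image: max/mean over slices of (mean, std, lacunarity) |
| I1–I5 | 5 | intensity histogram: mean, std, skewness, kurtosis, entropy |
| A1–A19 | 19 | angle co-occurrence matrix ACM1 (Sobel orientation pairs, l=1, 8 bins) |
| M1–M19 | 19 | ACM2 (gradient-magnitude-weighted orientation pairs) |

The ACM blocks capture *directional edge patterns*: with `S_a(i,j)` the
number and `S_m(i,j)` the magnitude-weighted sum of orientation-bin pairs
(i, j) at displacement (l, θ),

```
ACM1(i,j) = S_a(i,j) / Σ S_a,      ACM2(i,j) = S_m(i,j) / Σ S_m
```

normalized per direction and averaged over θ ∈ {0°, 45°, 90°, 135°}.

Selection ranks features incrementally by the fMRMR criterion

```
J(f_j) = MI(f_j; c) − (1/(m−1)) Σ_{f_i selected} MI(f_j; f_i)
```

with fuzzy mutual information computed from triangular quantile-based
membership partitions, then picks the subset size minimizing leave-one-out
naive-Bayes error.

## Worked example

```python
import tumortex as tx

cohort = tx.generate_cohort(tx.SyntheticCohortSpec(seed=11))   # 20 + 15 tumors
table = tx.build_cohort_table(cohort)                          # 35 x 255
for family in ("acm2", "ih", "all"):
    r = tx.loo_cv(table, family=family)
    print(f"{family:>5}: AUC={r.auc:.3f}  Ac={100*r.accuracy:.2f}%  "
          f"Sn={r.sensitivity:.2f}  Sp={r.specificity:.2f}")
```

prints

```
 acm2: AUC=1.000  Ac=97.14%  Sn=0.93  Sp=1.00
   ih: AUC=0.920  Ac=82.86%  Sn=0.93  Sp=0.75
  all: AUC=0.987  Ac=91.43%  Sn=0.87  Sp=0.95
```

On this synthetic cohort the class contrast is deliberately concentrated
in gradient-orientation coherence, so the directional-edge ACM2 family
separates the survival groups perfectly while the intensity histogram is
informative but weaker — the same edge-over-intensity ordering reported
for the clinical cohort.  Scores are out-of-fold naive-Bayes posteriors;
accuracy/sensitivity/specificity apply a 0.5 threshold with equal class
priors.

Short narrative scripts in `examples/` cover each capability (simulation,
extraction, selection, evaluation, the CLI equivalents).

## Command-line interface

```bash
tumortex simulate --n-short 20 --n-long 15 --seed 7 --out cohort/
tumortex extract  --manifest cohort/manifest.csv --out features.csv
tumortex select   --features features.csv --labels cohort/manifest.csv \
                  --family acm2 --out selection.json
tumortex evaluate --features features.csv --labels cohort/manifest.csv \
                  --family acm2 --cv loo --out results.json
```

## Scope

The package covers feature extraction, selection, and cross-validated
classification.  Image acquisition, tumor segmentation (masks are inputs),
survival-time statistics (Kaplan–Meier/Cox), SVM comparisons, and clinical
covariates are out of scope.  See `docs/methods.md` for the full model
description, parameter defaults, numerical conventions, and limitations.
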