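# Methods

This note documents the models, conventions, and design choices behind
`tumortex`: what each stage computes, which parameters matter, what the
synthetic data do and do not emulate, and where the implementation had to
decide things the feature definitions leave open.

## Unit of analysis and preprocessing

A tumor is a 3-D intensity volume with an aligned binary mask and voxel
spacing (metadata only; all features are in-plane and pixel-based, matching
the anisotropic CT geometry of 0.7324 × 0.7324 × 2.5 mm voxels).  Feature
extraction is 2-D: every axial slice whose mask holds at least `min_pixels`
(default 9) in-mask pixels is cropped to the mask bounding box and analysed
independently; per-slice features are averaged (unweighted by default;
in-mask-area weighting sits behind `area_weighted_slices`).  Slices that
clear `min_pixels` but contain no full 3×3 in-mask neighborhood cannot
support the gradient/pattern operators and are dropped with a warning, the
same way sub-threshold slices are.

Gray levels are quantized per slice into `N = 16` equal-width bins over the
in-mask min/max of that slice, the maximum mapping to level N and constant
slices to level 1.  The reference range is deliberately slice-relative
rather than a fixed HU window: the feature definitions only fix N, per-slice
min-max binning is the most common co-occurrence convention, and it makes
every quantized feature invariant to affine intensity rescaling.  Out-of-
mask pixels inside the bounding box carry the sentinel level 0 and never
enter any count.

## Texture families

**GLCM (G1–G19).**  Symmetric pair counting at distance `d = 2` pixels;
one matrix per direction {0°, 45°, 90°, 135°}, each normalized to a
probability matrix, then averaged.  Normalizing before averaging keeps
directions with fewer countable pairs (elongated masks) from being
down-weighted.  The 19 statistics are the 14 Haralick features in their
canonical order, then inertia, cluster shade, cluster prominence, Renyi
entropy of order `q = 8`, and Tsallis entropy of order `r = 2`.  Inertia
is Σ(i−j)²P(i,j) and numerically duplicates contrast; both are retained to
preserve the published 19-feature count, in which they are listed as
distinct features.  Conventions: all entropies are base-2 with 0·log 0 = 0;
sum variance is taken about the sum average; difference variance is the
variance of the |i−j| distribution; the information measures of correlation
use base-2 entropies throughout (f13's exponential form uses 2^(−2Δ), which
is identical to the natural-log form); the maximal correlation coefficient
is the square root of the second-largest eigenvalue magnitude of the Q
matrix restricted to levels with nonzero marginals, with a documented
fallback to 0 when fewer than two support levels exist — f14 is notoriously
unstable and the fallback keeps vectors finite.  The Tsallis entropy is
implemented exactly as printed, (1/(1−r)) Σ P^r, which for a delta matrix
gives −1 rather than the conventional (1 − Σ P^r)/(r−1) = 0; the
conventional form is available behind `tsallis_conventional` but is off by
default — the printed formula is reproduced, not silently corrected.

**Run-length matrices (R1–R11).**  Maximal constant-level runs along the
four directions, broken at mask boundaries (a hole splits a run).  The
cited feature count (11) is met with the standard Galloway-5 plus
Chu/Dasarathy-6 set: SRE, LRE, GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE,
LRLGE, LRHGE, each computed per direction and averaged.  Run percentage is
(number of runs)/(number of traversed in-mask pixels).

**LBP block (L1–L128).**  Codes threshold the eight 3×3 neighbors against
the center (ties set the bit, the original operator's convention, which
also makes constant regions well-defined: every code is 255), ordered
circularly starting east, counter-clockwise, east as the least significant
bit.  Only pixels with full in-mask 3×3 support are coded.  The block is:
59 ULBP bins (58 uniform patterns in ascending code order + pooled
non-uniform), 10 RI-ULBP bins (9 one-bit-count classes + non-uniform), 21
histogram statistics, and 38 histogram-Fourier values.  The 21 statistics
are {std, skewness, kurtosis, entropy} of the normalized histograms of
plain LBP (256 bins), ULBP, RI-ULBP, RI-LBP (36 min-rotation classes), and
rotated LBP (256 bins) — 20 values — plus the entropy of the ULBP
histogram-Fourier magnitude spectrum as the 21st: the published arithmetic
requires 21 descriptors while the enumeration yields 20, so the gap is
closed explicitly and the choice is isolated in the feature registry.  The
rotated-LBP variant shifts each code so the neighbor with the largest
absolute difference from the center sits at bit 0 (ties toward the lowest
neighbor index).  The HF block follows the standard P=8 construction:
|H(n,u)| for the seven non-constant uniform rows and u = 0..4 (35 values)
plus the three rotation-invariant singleton bins (all-zeros, all-ones,
non-uniform), the only decomposition that yields exactly 38.

**SFTA (F1_1–F1_48).**  Eight thresholds from a recursive two-level Otsu
scheme (the budget is split between the sub-ranges at each split), then 16
binary images: 8 gray-level *band* images cut at thresholds t2..t8 — the
lowest band extends down to the ROI minimum so the bands partition the
in-mask pixels — and 8 *upper* images I > t_i.  Per image: the box-counting
fractal dimension of its region borders (foreground pixels with a
background 4-neighbor; out-of-mask counts as background), the mean gray
level of the foreground, and the foreground pixel count, in that order.
Box counting uses dyadic sizes {1, 2, 4, 8} clipped to the ROI, an
origin-anchored grid, and an ordinary least-squares slope of log count
against log(1/size).  Degenerate ROIs with fewer distinct values than
thresholds produce fewer images; the missing ones contribute (0, 0, 0)
with a warning.  Mean/size are taken over the region foreground, the cited
method's convention, not over its border.

**DBC fractal-dimension image (F2_1–F2_6).**  For each pixel whose 7×7
window is fully in-mask, the window's intensity surface (relative to the
window minimum, which makes the estimate exactly shift-invariant) is
covered with boxes of side s ∈ {2, 3, 7} and height h = s·G/M, where G is
the slice's in-mask gray range and M = 7.  Since 7 is not divisible by 2
or 3, the per-box count ceil(max/h) − ceil(min/h) + 1 is averaged over the
complete s×s blocks and scaled by (M/s)²; this partial-block correction
makes a flat surface come out at dimension 2.0 exactly, which raw
ceil-partitioned counts do not.  The local dimension is the least-squares
slope of log N(s) versus log(1/r), r = s/M.  Per slice, the valid FD
values yield (mean, std, lacunarity), with lacunarity the moment form
E[X²]/E[X]² − 1; the six features are the max and the mean of each across
slices — the one family with its own cross-slice aggregation rule.

**Intensity histogram (I1–I5).**  Mean, population std, skewness, excess
kurtosis of in-mask intensities, and the entropy of a 16-bin equal-width
histogram over the in-mask range (16 matches the quantization depth;
nothing deeper is warranted at tumor-ROI pixel counts).  Zero-variance
ROIs return 0 for the shape statistics and the entropy.

**Angle co-occurrence matrices (A1–A19, M1–M19).**  Gradients come from
3×3 Sobel kernels evaluated only at pixels with full in-mask support, so
boundary pixels never contaminate the field; orientation is
atan2(gy, gx) in array coordinates mapped to [0°, 360°), quantized into
`n_theta = 8` equal 45° bins with bin 1 starting at 0° (zero-magnitude
pixels land in bin 1 via the atan2 convention).  Pairs at displacement
`l = 1` along the four directions are accumulated symmetrically —
occurrence counts for ACM1, weight magnitude(p) + magnitude(p′) for ACM2
(the literal reading of "sum of gradient magnitude responses of all
pixel-pairs") — normalized per direction, averaged, and passed through the
same 19 statistics as the GLCM.  When a gradient field is perfectly flat,
every ACM2 pair weight is zero and the printed normalization is 0/0; the
implementation falls back to occurrence counts, the zero-weight limit of
the identity "uniform magnitudes ⇒ ACM2 = ACM1".

A note on rotation: averaging over the four displacement directions makes
GLCM and RLM features exactly invariant to 90° image rotation.  ACM
matrices are instead *equivariant*: rotation shifts every orientation bin
by exactly two positions, cyclically relabeling rows and columns, so
label-free statistics (energy, the entropies) are invariant while
label-dependent ones (sum average, cluster shade, ...) legitimately
change.  The tests assert exactly this.  Similarly, constant intensity
shifts leave every feature unchanged except the intensity-histogram mean
and the 16 SFTA region mean-gray values, which shift by exactly the added
constant — they are gray-level means and cannot do otherwise.

## Feature selection

Features are fuzzified into a 3-set triangular partition of unity before
mutual information is computed.  Memberships are evaluated on the
empirical average-rank scale with set centers at the 10th/50th/90th
percentile positions: the cited fuzzy-MI constructions do not pin down the
membership system, and a small quantile-anchored partition is robust at
n = 35, fully testable, and makes the ranking exactly invariant to
strictly monotone transforms of any feature (ranks are).  Constant
features collapse to one set and carry zero information.  The class vector
is crisp two-set membership.  MI uses fuzzy joint frequencies
p(i,j) = (1/n) Σ_s a_si·b_sj, base-2 logs, clipped at 0.

Ranking is the incremental criterion J(f_j) = MI(f_j; c) − mean MI with the
already-selected set; the first feature is simply the most class-relevant
one, and ties break toward the lowest feature index for determinism.  The
redundancy sums are cached and updated with one vectorized pass per step,
so a full 255-feature ranking is O(D²) mutual-information evaluations
computed in ~255 einsum calls.

Forward selection computes, for k = 1..k_max, the leave-one-out
misclassification rate of the naive-Bayes classifier on the first k ranked
features and returns the smallest k attaining the minimum.  `k_max`
defaults to min(D, n−2) so every internal training fold keeps at least two
samples per class and the variance estimates defined.  The internal LOO
uses exact closed-form downdates of the per-class moments, making the n
refits cost O(n·d) in total.

## Classification and evaluation

Gaussian naive Bayes with equal class priors; per-class, per-feature means
and variances, the latter floored at 1e-9 times the pooled feature
variance (plus 1e-12 absolute) so post-selection degenerate features cannot
produce infinite likelihoods.  Posteriors are computed in the log domain.
The positive class (label 1) is survival ≥ 2 years; accuracy, sensitivity
(recall of label 1), and specificity (recall of label 0) apply a 0.5
posterior threshold with ties classified positive.  AUC is the trapezoidal
area, identical to the Mann-Whitney rank statistic with ties counted ½.

Two protocols: leave-one-image-out, and stratified 3-fold cross-validation
repeated 20 times with fresh seeded partitions.  In both, the fMRMR
ranking *and* the forward selection are re-run inside every training fold;
held-out rows never reach fuzzification, ranking, selection, or fitting
(the test suite asserts this by instrumentation).  Stratification is used
because unstratified 3-fold splits of a 20/15 cohort can produce
single-class training folds; repeats are aggregated by computing the four
metrics on each repeat's pooled out-of-fold scores and averaging over
repeats, which makes k = n reduce exactly to leave-one-out.

## Synthetic data

The generator emulates the *structure* of the study data, not CT physics:
ellipsoidal tumors (defaults: 32×32×8 voxel grids, 3–6 slice extents,
in-plane diameters 55–80% of the matrix, ~1–3 cm³ at the study voxel
size) on a pseudo-HU scale centered at 70 with a smooth shared background
field (sd 5) and additive white noise (sd 2).  The label contrast is a
texture regime scaled by `texture_effect` ∈ [0, 1]:

* label 0 (survival < 2 years): band-pass noise (wavelength 3.5–5.5 px)
  whose spectral power is concentrated in a random orientation wedge
  (angular sd 0.25 rad), plus 1–3 hypointense necrosis-like blobs (depth
  35 at full effect) — strong, directionally coherent edges;
* label 1 (survival ≥ 2 years): isotropic band-pass noise at a lower
  center frequency (wavelength 7–10 px) — matched marginal variance
  (sd 16 at full effect), incoherent gradients.

Matching the marginal variance concentrates the class contrast in
*directional* structure, which is what makes the edge-based ACM families
the discriminative axis and reproduces the reported edge-over-intensity
ordering; the blobs leave the intensity histogram moderately informative
rather than blind.  At `texture_effect = 0` the regime component vanishes
and — because shared components consume the RNG stream first — the two
labels produce bit-identical volumes for the same seed: the null
calibration really is label-exchangeable.  Per-tumor streams are hashed
from (cohort seed, patient index), so cohorts are reproducible under
partial regeneration.  The generator makes no claim about PDAC biology:
passing tests show the pipeline recovers planted texture contrasts of this
kind, not that it predicts survival in patients.

`planted_feature_table` serves the selection-recovery experiment: two
complementary columns track the label except on disjoint trios of
short survivors where each is flipped; alone either column misclassifies
its trio, together they separate perfectly, so the optimal subset size is
exactly 2 by construction.

## Problem sizes

The shipped experiments run on reduced problem sizes chosen to keep the
full suite fast while leaving every operator well-supported: 32×32×8
volumes (a 7×7 DBC window still fits dozens of valid pixels per slice),
35-patient cohorts, 20 null cohorts for calibration, 20 replicates for
selection recovery.  All randomness flows from explicit seeds;
cross-validation partitions are seeded per repeat.

## Known limitations

* No 3-D texture variants, DICOM handling, resampling, or HU calibration;
  masks are inputs, segmentation is out of scope.
* The S1-style authoritative name list for the 255 features is not
  reproduced in the main text of the source method; the registry
  reconstructs it from the per-family counts and ordering and should be
  treated as reconstructed, not transcribed.
* f14 (maximal correlation coefficient) and the 21st LBP statistic are the
  two places where a documented local convention stands in for an
  under-specified definition; both are isolated so they can be swapped
  without touching other features.
* Clinical performance numbers cannot be reproduced without the original
  cohort; the synthetic experiments validate structure, calibration, and
  relative family ordering only.
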