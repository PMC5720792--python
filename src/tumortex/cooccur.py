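"""Co-occurrence texture families: GLCM, run-length matrices, and angle
co-occurrence matrices (ACM) built from Sobel gradient orientations.

All three families share the same conventions:

* pairs/runs contribute only when every involved pixel is in-mask (for ACM,
  additionally *valid*, i.e. its full 3x3 Sobel support is in-mask);
* pair counting is symmetric (each pair is counted in both directions), so
  every co-occurrence matrix satisfies P == P.T;
* one matrix is formed per displacement direction, normalized to a
  probability matrix, and the four directional matrices {0, 45, 90, 135}
  degrees are averaged into a single resultant matrix;
* all entropies are base-2 and use the 0 * log 0 = 0 convention.

From each resultant matrix a fixed ordered set of 19 statistics is taken:
the 14 Haralick features (energy, contrast, correlation, variance, inverse
difference moment, sum average, sum variance, sum entropy, entropy,
difference variance, difference entropy, the two information measures of
correlation, and the maximal correlation coefficient), followed by inertia,
cluster shade, cluster prominence, Renyi entropy of order q and Tsallis
entropy of order r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import DegenerateROIError, ParameterError
from .image_io import QuantizedROI, SliceROI

STAT_NAMES: Tuple[str, ...] = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "max_correlation_coefficient",
    "inertia",
    "cluster_shade",
    "cluster_prominence",
    "renyi_entropy",
    "tsallis_entropy",
)


@dataclass
class CooccurrenceMatrix:
    """Normalized joint-occurrence probability matrix (GLCM or ACM)."""

    P: np.ndarray
    N: int
    kind: str  # "glcm" | "acm1" | "acm2"


@dataclass
class RunLengthMatrix:
    """Gray level x run length counts for one direction."""

    R: np.ndarray  # (N, Lmax) integer counts
    direction: int


@dataclass
class GradientField:
    """Sobel gradient orientation/magnitude restricted to interior pixels."""

    angle: np.ndarray  # degrees in [0, 360)
    magnitude: np.ndarray
    valid: np.ndarray  # bool; full 3x3 in-mask support


def _offset(angle: int, d: int) -> Tuple[int, int]:
    """Displacement (drow, dcol) in array coordinates for a direction.

    0 deg is along +columns; angles increase counter-clockwise in image
    display convention (rows grow downward), so 45 deg is up-right.
    """
    if angle == 0:
        return (0, d)
    if angle == 45:
        return (-d, d)
    if angle == 90:
        return (-d, 0)
    if angle == 135:
        return (-d, -d)
    raise ParameterError(f"unsupported direction {angle}; use 0/45/90/135")


def _shifted_views(a: np.ndarray, dr: int, dc: int):
    """Views of `a` at positions p and p + (dr, dc), both inside the array."""
    nr, nc = a.shape
    r0, r1 = max(0, -dr), min(nr, nr - dr)
    c0, c1 = max(0, -dc), min(nc, nc - dc)
    if r0 >= r1 or c0 >= c1:
        empty = a[0:0, 0:0]
        return empty, empty
    return a[r0:r1, c0:c1], a[r0 + dr : r1 + dr, c0 + dc : c1 + dc]


def _pair_histogram(
    codes: np.ndarray,
    ok: np.ndarray,
    n_bins: int,
    dr: int,
    dc: int,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Symmetric co-occurrence accumulation of `codes` (0-based bins)."""
    a, b = _shifted_views(codes, dr, dc)
    ma, mb = _shifted_views(ok, dr, dc)
    sel = ma & mb
    ia, ib = a[sel], b[sel]
    if weights is None:
        w = np.ones(ia.size)
    else:
        wa, wb = _shifted_views(weights, dr, dc)
        w = wa[sel] + wb[sel]
    S = np.zeros((n_bins, n_bins))
    np.add.at(S, (ia, ib), w)
    np.add.at(S, (ib, ia), w)
    return S


def compute_glcm(
    qroi: QuantizedROI,
    d: int = 2,
    angles: Sequence[int] = (0, 45, 90, 135),
) -> CooccurrenceMatrix:
    """Four-direction-averaged, symmetric, normalized GLCM.

    Each directional matrix is normalized to a probability matrix first and
    the directional matrices are then averaged, so directions with fewer
    countable pairs are not down-weighted.
    """
    if d < 1:
        raise ParameterError("distance d must be >= 1")
    codes = qroi.levels - 1  # 0-based; out-of-mask becomes -1, excluded via mask
    ok = qroi.mask
    mats = []
    for ang in angles:
        dr, dc = _offset(ang, d)
        S = _pair_histogram(codes, ok, qroi.N, dr, dc)
        tot = S.sum()
        if tot > 0:
            mats.append(S / tot)
    if not mats:
        raise DegenerateROIError("no in-mask pixel pair at any direction")
    P = np.mean(mats, axis=0)
    return CooccurrenceMatrix(P=P, N=qroi.N, kind="glcm")


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def cooccurrence_stats19(
    M: CooccurrenceMatrix,
    q: float = 8.0,
    r: float = 2.0,
    tsallis_conventional: bool = False,
) -> np.ndarray:
    """The ordered 19 statistics of a normalized co-occurrence matrix.

    The Renyi entropy is (1/(1-q)) log2 sum(P^q).  The Tsallis entropy is
    reproduced in its printed form (1/(1-r)) sum(P^r) by default; the
    conventional (1 - sum(P^r))/(r - 1) form is available behind a flag.
    Degenerate marginals (zero variance) yield correlation 0 and a maximal
    correlation coefficient of 0 rather than NaN.
    """
    P = M.P
    N = P.shape[0]
    i = np.arange(1, N + 1)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float(i @ px)
    muy = float(i @ py)
    sx = float(np.sqrt(((i - mux) ** 2) @ px))
    sy = float(np.sqrt(((i - muy) ** 2) @ py))

    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj

    energy = float((P**2).sum())
    contrast = float(((diff**2) * P).sum())
    if sx > 0 and sy > 0:
        correlation = float(((ii * jj * P).sum() - mux * muy) / (sx * sy))
    else:
        correlation = 0.0
    variance = float((((ii - mux) ** 2) * P).sum())
    idm = float((P / (1.0 + diff**2)).sum())

    # p_{x+y}(k), k = 2..2N and p_{x-y}(k), k = 0..N-1
    ksum = (ii + jj).ravel()
    kdiff = np.abs(diff).ravel()
    p_sum = np.bincount(ksum, weights=P.ravel(), minlength=2 * N + 1)[2:]
    p_dif = np.bincount(kdiff, weights=P.ravel(), minlength=N)
    ks = np.arange(2, 2 * N + 1)
    kd = np.arange(N)
    sum_average = float(ks @ p_sum)
    sum_variance = float(((ks - sum_average) ** 2) @ p_sum)
    sum_entropy = _entropy2(p_sum)
    entropy = _entropy2(P.ravel())
    mu_d = float(kd @ p_dif)
    difference_variance = float(((kd - mu_d) ** 2) @ p_dif)
    difference_entropy = _entropy2(p_dif)

    hx = _entropy2(px)
    hy = _entropy2(py)
    outer = np.outer(px, py)
    mask_pos = (P > 0) & (outer > 0)
    hxy1 = float(-(P[mask_pos] * np.log2(outer[mask_pos])).sum())
    pos_o = outer > 0
    hxy2 = float(-(outer[pos_o] * np.log2(outer[pos_o])).sum())
    denom = max(hx, hy)
    imc1 = float((entropy - hxy1) / denom) if denom > 0 else 0.0
    inner = 1.0 - 2.0 ** (-2.0 * (hxy2 - entropy))
    imc2 = float(np.sqrt(max(inner, 0.0)))

    mcc = _max_correlation_coefficient(P, px, py)

    inertia = contrast
    csum = ii + jj - mux - muy
    cluster_shade = float(((csum**3) * P).sum())
    cluster_prominence = float(((csum**4) * P).sum())

    ppos = P[P > 0]
    renyi = float(np.log2((ppos**q).sum()) / (1.0 - q))
    if tsallis_conventional:
        tsallis = float((1.0 - (ppos**r).sum()) / (r - 1.0))
    else:
        tsallis = float((ppos**r).sum() / (1.0 - r))

    return np.array(
        [
            energy,
            contrast,
            correlation,
            variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
            difference_entropy,
            imc1,
            imc2,
            mcc,
            inertia,
            cluster_shade,
            cluster_prominence,
            renyi,
            tsallis,
        ]
    )


def _max_correlation_coefficient(P: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    """Square root of the second largest eigenvalue of the Haralick Q matrix.

    Restricted to gray levels with nonzero marginals; returns 0 when the
    coefficient is numerically undefined (fewer than two support levels or a
    failed eigendecomposition) -- f14 is notoriously unstable and a fixed
    fallback keeps feature vectors finite.
    """
    sup_x = px > 0
    sup_y = py > 0
    if sup_x.sum() < 2 or sup_y.sum() < 2:
        return 0.0
    Ps = P[np.ix_(sup_x, sup_y)]
    A = Ps / px[sup_x][:, None]
    B = Ps / py[sup_y][None, :]
    Q = A @ B.T
    try:
        ev = np.linalg.eigvals(Q)
    except np.linalg.LinAlgError:
        return 0.0
    mags = np.sort(np.abs(ev))[::-1]
    if mags.size < 2 or not np.isfinite(mags[1]):
        return 0.0
    return float(np.sqrt(min(max(mags[1], 0.0), 1.0)))


# ---------------------------------------------------------------------------
# Run-length matrices
# ---------------------------------------------------------------------------


def _direction_lines(a: np.ndarray, direction: int) -> Iterable[np.ndarray]:
    """1-D scan lines of `a` along a direction (runs ignore the sign)."""
    nr, nc = a.shape
    if direction == 0:
        for r in range(nr):
            yield a[r, :]
    elif direction == 90:
        for c in range(nc):
            yield a[:, c]
    elif direction == 135:
        # constant r - c (down-right diagonals)
        for off in range(-nr + 1, nc):
            yield np.diagonal(a, offset=off)
    elif direction == 45:
        # constant r + c (up-right anti-diagonals)
        f = a[::-1, :]
        for off in range(-nr + 1, nc):
            yield np.diagonal(f, offset=off)
    else:
        raise ParameterError(f"unsupported direction {direction}")


def _run_lengths(line: np.ndarray) -> Iterable[Tuple[int, int]]:
    """Maximal constant-level runs of a scan line; level 0 (out-of-mask) breaks runs."""
    n = line.size
    if n == 0:
        return
    change = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [n]))
    for s, e in zip(starts, ends):
        lev = int(line[s])
        if lev > 0:
            yield lev, int(e - s)


def compute_rlm(qroi: QuantizedROI, direction: int) -> RunLengthMatrix:
    """Run-length counts R(level, length) along one direction.

    Runs break at mask boundaries (holes split a run in two).
    """
    if not qroi.mask.any():
        raise DegenerateROIError("empty mask")
    lmax = max(qroi.levels.shape)
    R = np.zeros((qroi.N, lmax), dtype=np.int64)
    for line in _direction_lines(qroi.levels, direction):
        for lev, ln in _run_lengths(np.asarray(line)):
            R[lev - 1, ln - 1] += 1
    return RunLengthMatrix(R=R, direction=direction)


RLM_FEATURE_NAMES: Tuple[str, ...] = (
    "short_run_emphasis",
    "long_run_emphasis",
    "gray_level_nonuniformity",
    "run_length_nonuniformity",
    "run_percentage",
    "low_gray_run_emphasis",
    "high_gray_run_emphasis",
    "short_run_low_gray_emphasis",
    "short_run_high_gray_emphasis",
    "long_run_low_gray_emphasis",
    "long_run_high_gray_emphasis",
)


def _rlm_stats(R: np.ndarray) -> np.ndarray:
    """The classical 11 run-length statistics of one directional matrix."""
    Rf = R.astype(float)
    n_runs = Rf.sum()
    if n_runs == 0:
        return np.zeros(11)
    N, L = Rf.shape
    g = np.arange(1, N + 1)[:, None].astype(float)
    ln = np.arange(1, L + 1)[None, :].astype(float)
    n_pix = float((Rf * ln).sum())
    sre = (Rf / ln**2).sum() / n_runs
    lre = (Rf * ln**2).sum() / n_runs
    gln = (Rf.sum(axis=1) ** 2).sum() / n_runs
    rln = (Rf.sum(axis=0) ** 2).sum() / n_runs
    rp = n_runs / n_pix
    lgre = (Rf / g**2).sum() / n_runs
    hgre = (Rf * g**2).sum() / n_runs
    srlge = (Rf / (g**2 * ln**2)).sum() / n_runs
    srhge = (Rf * g**2 / ln**2).sum() / n_runs
    lrlge = (Rf * ln**2 / g**2).sum() / n_runs
    lrhge = (Rf * g**2 * ln**2).sum() / n_runs
    return np.array([sre, lre, gln, rln, rp, lgre, hgre, srlge, srhge, lrlge, lrhge])


def rlm_features(qroi: QuantizedROI, angles: Sequence[int] = (0, 45, 90, 135)) -> np.ndarray:
    """The 11 run-length features, averaged over the four directions."""
    stats = [_rlm_stats(compute_rlm(qroi, a).R) for a in angles]
    return np.mean(stats, axis=0)


# ---------------------------------------------------------------------------
# Gradient field and angle co-occurrence matrices
# ---------------------------------------------------------------------------

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_SOBEL_Y = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float)


def sobel_gradients(roi: SliceROI) -> GradientField:
    """3x3 Sobel gradient orientation and magnitude on interior pixels.

    Boundary pixels -- those whose 3x3 neighborhood leaves the mask -- are
    flagged invalid and never processed, so values outside the tumor cannot
    contaminate the gradient field.  The orientation convention is
    atan2(gy, gx) in array coordinates (0 deg along +columns), mapped to
    [0, 360).
    """
    valid = ndimage.binary_erosion(roi.mask, structure=np.ones((3, 3), dtype=bool))
    if not valid.any():
        raise DegenerateROIError("no pixel has full 3x3 in-mask support")
    gx = ndimage.correlate(roi.intensities, _SOBEL_X, mode="constant")
    gy = ndimage.correlate(roi.intensities, _SOBEL_Y, mode="constant")
    angle = np.degrees(np.arctan2(gy, gx)) % 360.0
    magnitude = np.hypot(gx, gy)
    angle[~valid] = 0.0
    magnitude[~valid] = 0.0
    return GradientField(angle=angle, magnitude=magnitude, valid=valid)


def compute_acm(
    field: GradientField,
    l: int = 1,
    n_theta: int = 8,
    weighted: bool = False,
    angles: Sequence[int] = (0, 45, 90, 135),
) -> CooccurrenceMatrix:
    """Angle co-occurrence matrix of quantized gradient orientations.

    Orientations are binned into ``n_theta`` equal sectors of [0, 360), bin 1
    starting at 0 deg; zero-magnitude pixels fall in bin 1 by the atan2
    convention.  For each displacement (l, theta) the pair histogram over
    orientation bins is accumulated symmetrically -- unweighted occurrence
    counts for ACM1, or pair weights mag(p) + mag(p') for ACM2 -- normalized
    to a probability matrix, and the four directional matrices are averaged.
    """
    if l < 1:
        raise ParameterError("displacement l must be >= 1")
    width = 360.0 / n_theta
    bins = np.minimum((field.angle // width).astype(np.int64), n_theta - 1)
    mats = []
    for ang in angles:
        dr, dc = _offset(ang, l)
        S = _pair_histogram(
            bins,
            field.valid,
            n_theta,
            dr,
            dc,
            weights=field.magnitude if weighted else None,
        )
        if weighted and S.sum() == 0:
            # a perfectly flat field weights every pair 0; zero weights are
            # uniform weights, so fall back to occurrence counts (= ACM1)
            S = _pair_histogram(bins, field.valid, n_theta, dr, dc)
        tot = S.sum()
        if tot > 0:
            mats.append(S / tot)
    if not mats:
        raise DegenerateROIError("no valid pixel pair at any direction")
    P = np.mean(mats, axis=0)
    return CooccurrenceMatrix(P=P, N=n_theta, kind="acm2" if weighted else "acm1")


def acm_feature_block(
    roi: SliceROI,
    l: int = 1,
    n_theta: int = 8,
    q: float = 8.0,
    r: float = 2.0,
    angles: Sequence[int] = (0, 45, 90, 135),
    tsallis_conventional: bool = False,
) -> np.ndarray:
    """The 38 directional-edge features: 19 statistics each of ACM1 and ACM2."""
    field = sobel_gradients(roi)
    out: List[np.ndarray] = []
    for weighted in (False, True):
        M = compute_acm(field, l=l, n_theta=n_theta, weighted=weighted, angles=angles)
        out.append(cooccurrence_stats19(M, q=q, r=r, tsallis_conventional=tsallis_conventional))
    return np.concatenate(out)
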