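"""Local binary patterns (128-feature block) and first-order intensity
histogram features.

The LBP code of a pixel thresholds its eight 3x3 neighbors against the
center (ties count as 1), orders them circularly starting east and running
counter-clockwise, and reads the bits as an 8-bit integer (east = least
significant bit).  Only pixels whose full 3x3 neighborhood is in-mask are
coded.  From the code map the block assembles:

* L1-L59    normalized uniform-LBP histogram (58 uniform patterns in
            ascending code order + 1 pooled non-uniform bin);
* L60-L69   normalized rotation-invariant uniform-LBP histogram (9 one-bit
            count classes + 1 non-uniform bin);
* L70-L90   four statistics (standard deviation, skewness, kurtosis,
            entropy) of the normalized histograms of plain LBP (256 bins),
            ULBP (59), RI-ULBP (10), RI-LBP (36) and rotated LBP (256),
            plus the entropy of the ULBP histogram-Fourier magnitude
            spectrum as the 21st descriptor;
* L91-L128  LBP histogram-Fourier features for P=8: |H(n, u)| for the seven
            non-constant uniform rows (u = 0..4, 35 values) plus the three
            rotation-invariant singleton bins (all-zeros, all-ones,
            non-uniform).

Every LBP feature depends only on intensity *orderings* within 3x3
neighborhoods, so the whole block is bit-exactly invariant to adding a
constant to the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .errors import DegenerateROIError
from .image_io import SliceROI

# Neighbor offsets (drow, dcol): east, then counter-clockwise (display
# convention: rows grow downward, so counter-clockwise means north is -row).
NEIGHBOR_OFFSETS = (
    (0, 1),
    (-1, 1),
    (-1, 0),
    (-1, -1),
    (0, -1),
    (1, -1),
    (1, 0),
    (1, 1),
)

P = 8  # neighbors per pixel


def _transitions(code: int) -> int:
    bits = [(code >> k) & 1 for k in range(P)]
    return sum(bits[k] != bits[(k + 1) % P] for k in range(P))


def _rotate_code(code: int, shift: int) -> int:
    """Circular right shift: bit k of the result is bit (k + shift) mod P."""
    shift %= P
    return ((code >> shift) | (code << (P - shift))) & 0xFF


def _build_tables():
    uniform_codes = sorted(c for c in range(256) if _transitions(c) <= 2)
    ulbp_index = np.full(256, len(uniform_codes), dtype=np.int64)  # 58 -> non-uniform
    for k, c in enumerate(uniform_codes):
        ulbp_index[c] = k
    ri_code = np.array(
        [min(_rotate_code(c, s) for s in range(P)) for c in range(256)], dtype=np.int64
    )
    ri_classes = np.unique(ri_code)  # 36 rotation classes
    ri_index = np.searchsorted(ri_classes, ri_code)
    riu_index = np.full(256, P + 1, dtype=np.int64)  # bin 9 -> non-uniform
    for c in range(256):
        if _transitions(c) <= 2:
            riu_index[c] = bin(c).count("1")
    return np.array(uniform_codes), ulbp_index, ri_code, ri_index, riu_index


_UNIFORM_CODES, _ULBP_INDEX, _RI_CODE, _RILBP_INDEX, _RIULBP_INDEX = _build_tables()

N_ULBP_BINS = 59
N_RIULBP_BINS = 10
N_RILBP_BINS = 36


@dataclass
class LBPMaps:
    """Per-pixel LBP code variants on the valid interior of an ROI."""

    lbp: np.ndarray  # plain 8-bit code
    ri_lbp: np.ndarray  # minimum circular rotation of the code
    rot_lbp: np.ndarray  # code aligned to the dominant-difference neighbor
    valid: np.ndarray  # bool


def lbp_code_maps(roi: SliceROI) -> LBPMaps:
    """Compute plain, rotation-invariant, and dominant-rotation LBP codes.

    The rotated-LBP variant circularly shifts each code so that the neighbor
    with the largest absolute intensity difference from the center sits at
    bit position 0 (ties resolved toward the lowest neighbor index), making
    the code approximately rotation invariant while retaining more pattern
    detail than the min-rotation code.
    """
    valid = ndimage.binary_erosion(roi.mask, structure=np.ones((3, 3), dtype=bool))
    if not valid.any():
        raise DegenerateROIError("no pixel has full 3x3 in-mask support")
    img = roi.intensities
    nr, nc = img.shape
    center = img[1 : nr - 1, 1 : nc - 1]
    bits = np.zeros((P,) + center.shape, dtype=np.int64)
    absdiff = np.zeros((P,) + center.shape)
    for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        nb = img[1 + dr : nr - 1 + dr, 1 + dc : nc - 1 + dc]
        bits[k] = (nb >= center).astype(np.int64)
        absdiff[k] = np.abs(nb - center)
    weights = (1 << np.arange(P, dtype=np.int64))[:, None, None]
    code_in = (bits * weights).sum(axis=0)
    dom = absdiff.argmax(axis=0)  # argmax takes the lowest index on ties
    # rotated code: bit k of the result = bit (k + dom) mod P of the original
    rot_in = np.zeros_like(code_in)
    for k in range(P):
        bit_k = np.take_along_axis(bits, ((k + dom) % P)[None, :, :], axis=0)[0]
        rot_in |= bit_k << k

    lbp = np.zeros(img.shape, dtype=np.int64)
    lbp[1 : nr - 1, 1 : nc - 1] = code_in
    rot = np.zeros(img.shape, dtype=np.int64)
    rot[1 : nr - 1, 1 : nc - 1] = rot_in
    ri = np.zeros(img.shape, dtype=np.int64)
    ri[1 : nr - 1, 1 : nc - 1] = _RI_CODE[code_in]
    lbp[~valid] = 0
    rot[~valid] = 0
    ri[~valid] = 0
    return LBPMaps(lbp=lbp, ri_lbp=ri, rot_lbp=rot, valid=valid)


def _norm_hist(values: np.ndarray, n_bins: int) -> np.ndarray:
    h = np.bincount(values, minlength=n_bins).astype(float)
    tot = h.sum()
    return h / tot if tot > 0 else h


def _hist_stats(h: np.ndarray) -> np.ndarray:
    """std / skewness / kurtosis of the probability vector + its entropy."""
    sd = float(np.std(h))
    if sd > 0:
        sk = float(stats.skew(h))
        ku = float(stats.kurtosis(h))  # excess kurtosis
    else:
        sk, ku = 0.0, 0.0
    pos = h[h > 0]
    ent = float(-(pos * np.log2(pos)).sum()) if pos.size else 0.0
    return np.array([sd, sk, ku, ent])


def _uniform_rows(ulbp_hist: np.ndarray) -> np.ndarray:
    """Reshape the uniform-pattern histogram into 7 rows of 8 rotations.

    Row n (n = 1..7 ones) holds the frequencies of U(n, r) = the n-ones
    contiguous pattern rotated by r, for r = 0..7.
    """
    rows = np.zeros((P - 1, P))
    code_to_bin = {int(c): k for k, c in enumerate(_UNIFORM_CODES)}
    for n in range(1, P):
        base = (1 << n) - 1
        for r in range(P):
            code = ((base << r) | (base >> (P - r))) & 0xFF if r else base
            rows[n - 1, r] = ulbp_hist[code_to_bin[code]]
    return rows


@dataclass
class LBPFeatureBlock:
    ulbp_hist: np.ndarray  # 59
    ri_ulbp_hist: np.ndarray  # 10
    hist_stats: np.ndarray  # 21
    hf: np.ndarray  # 38

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.ulbp_hist, self.ri_ulbp_hist, self.hist_stats, self.hf])


def lbp_feature_block(roi: SliceROI) -> LBPFeatureBlock:
    """Assemble the 128 LBP descriptors of one slice ROI."""
    maps = lbp_code_maps(roi)
    v = maps.valid
    codes = maps.lbp[v]
    h_lbp = _norm_hist(codes, 256)
    h_ulbp = np.zeros(N_ULBP_BINS)
    np.add.at(h_ulbp, _ULBP_INDEX[codes], 1.0)
    h_ulbp /= max(h_ulbp.sum(), 1.0)
    h_riulbp = np.zeros(N_RIULBP_BINS)
    np.add.at(h_riulbp, _RIULBP_INDEX[codes], 1.0)
    h_riulbp /= max(h_riulbp.sum(), 1.0)
    h_rilbp = np.zeros(N_RILBP_BINS)
    np.add.at(h_rilbp, _RILBP_INDEX[codes], 1.0)
    h_rilbp /= max(h_rilbp.sum(), 1.0)
    h_rot = _norm_hist(maps.rot_lbp[v], 256)

    rows = _uniform_rows(h_ulbp)
    H = np.fft.fft(rows, axis=1)
    hf_mags = np.abs(H[:, : P // 2 + 1])  # u = 0..4
    nonuniform_mass = float(h_ulbp[-1])
    all_zeros = float(h_ulbp[0])  # code 0 is the first uniform code
    all_ones_bin = int(np.searchsorted(_UNIFORM_CODES, 255))
    all_ones = float(h_ulbp[all_ones_bin])
    hf = np.concatenate([hf_mags.ravel(), [all_zeros, all_ones, nonuniform_mass]])

    spec = hf_mags.ravel()
    tot = spec.sum()
    if tot > 0:
        p = spec[spec > 0] / tot
        hf_entropy = float(-(p * np.log2(p)).sum())
    else:
        hf_entropy = 0.0
    hstats = np.concatenate(
        [
            _hist_stats(h_lbp),
            _hist_stats(h_ulbp),
            _hist_stats(h_riulbp),
            _hist_stats(h_rilbp),
            _hist_stats(h_rot),
            [hf_entropy],
        ]
    )
    return LBPFeatureBlock(ulbp_hist=h_ulbp, ri_ulbp_hist=h_riulbp, hist_stats=hstats, hf=hf)


def intensity_histogram_features(roi: SliceROI, n_bins: int = 16) -> np.ndarray:
    """Mean, standard deviation, skewness, excess kurtosis, and histogram
    entropy of the in-mask intensities.

    The entropy uses ``n_bins`` equal-width bins over the in-mask range.
    Zero-variance ROIs return skewness = kurtosis = entropy = 0.
    """
    vals = roi.intensities[roi.mask].astype(float)
    mean = float(vals.mean())
    sd = float(vals.std())
    if sd > 0:
        sk = float(stats.skew(vals))
        ku = float(stats.kurtosis(vals))
        h, _ = np.histogram(vals, bins=n_bins, range=(vals.min(), vals.max()))
        p = h[h > 0] / h.sum()
        ent = float(-(p * np.log2(p)).sum())
    else:
        sk, ku, ent = 0.0, 0.0, 0.0
    return np.array([mean, sd, sk, ku, ent])
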