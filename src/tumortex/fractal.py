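"""Fractal texture features: segmentation-based fractal texture analysis
(SFTA) and a per-pixel differential box-counting (DBC) fractal-dimension
image.

SFTA decomposes the ROI into 16 binary images (8 gray-level band images
that partition the in-mask intensity range, plus 8 upper-threshold images)
using thresholds from a recursive multi-level Otsu scheme.  Each binary
image contributes three values -- the box-counting fractal dimension of its
region borders, the mean gray level of its region, and its pixel count --
for 48 features in total.

DBC treats each (default 7x7) window around a pixel as a 3-D intensity
surface, counts the boxes of side s (heights scaled to the gray range)
needed to cover the surface, and estimates the local fractal dimension as
the least-squares slope of log N(s) against log(1/r) with r = s/M.  Partial
boxes at the window edge are handled by estimating the per-box count from
complete s x s blocks and scaling to the full window area, which makes a
flat surface come out at dimension 2 exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import DegenerateROIError
from .image_io import SliceROI


@dataclass
class FDImage:
    """Per-pixel local fractal dimension over valid (full-window) pixels."""

    fd: np.ndarray
    valid: np.ndarray


# ---------------------------------------------------------------------------
# SFTA
# ---------------------------------------------------------------------------


def _otsu_recursive(values: np.ndarray, k: int) -> List[float]:
    """k thresholds by recursively splitting the value range with Otsu.

    Mirrors the multi-level scheme of the original SFTA method: the two-level
    Otsu threshold splits the data, and the remaining threshold budget is
    divided between the halves.  Degenerate regions (fewer than two distinct
    values) simply contribute fewer thresholds.
    """
    if k <= 0 or values.size < 2 or np.unique(values).size < 2:
        return []
    try:
        t = float(threshold_otsu(values, nbins=128))
    except ValueError:
        return []
    left = values[values <= t]
    right = values[values > t]
    k_left = (k - 1) // 2
    k_right = k - 1 - k_left
    return sorted(_otsu_recursive(left, k_left) + [t] + _otsu_recursive(right, k_right))


def box_counting_dimension(
    points: np.ndarray, box_sizes: Sequence[int] = (1, 2, 4, 8)
) -> float:
    """Box-counting dimension of a 2-D binary point set.

    Counts boxes of each (dyadic) size containing at least one point on a
    grid anchored at the array origin; the dimension is the least-squares
    slope of log(count) versus log(1/size).  Empty sets return 0.
    """
    if not points.any():
        return 0.0
    rr, cc = np.nonzero(points)
    max_dim = max(points.shape)
    sizes = [s for s in box_sizes if s <= max_dim]
    if len(sizes) < 2:
        sizes = [1, 2]
    counts = []
    for s in sizes:
        boxes = set(zip(rr // s, cc // s))
        counts.append(len(boxes))
    x = np.log(1.0 / np.asarray(sizes, dtype=float))
    y = np.log(np.asarray(counts, dtype=float))
    slope = np.polyfit(x, y, 1)[0]
    return float(slope)


def _region_borders(fg: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one background 4-neighbor.

    Pixels beyond the array edge count as background, so region outlines at
    the bounding-box edge are borders too.
    """
    core = ndimage.binary_erosion(
        fg, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
        border_value=0,
    )
    return fg & ~core


def sfta_binary_images(
    roi: SliceROI, n_thresholds: int = 8
) -> Tuple[List[np.ndarray], List[float]]:
    """The 2 * n_thresholds SFTA binary images and their Otsu thresholds.

    The first ``n_thresholds`` images are gray-level *band* images: the ROI
    range cut at thresholds t2..t_k, with the lowest band extended down to
    the ROI minimum so the bands partition the in-mask pixels.  The second
    ``n_thresholds`` are *upper* images I > t_i.  Degenerate ROIs (too few
    distinct values) yield fewer thresholds; missing images are empty and a
    warning is emitted.
    """
    vals = roi.intensities[roi.mask]
    thresholds = _otsu_recursive(vals, n_thresholds)
    if len(thresholds) < n_thresholds:
        warnings.warn(
            "degenerate ROI: only %d of %d SFTA thresholds found"
            % (len(thresholds), n_thresholds),
            stacklevel=2,
        )
    binaries: List[np.ndarray] = []
    # band images: cuts at thresholds[1:], lowest band absorbs everything below
    cuts = thresholds[1:]
    edges = [-np.inf] + list(cuts) + [np.inf]
    for lo, hi in zip(edges[:-1], edges[1:]):
        binaries.append(roi.mask & (roi.intensities > lo) & (roi.intensities <= hi))
    while len(binaries) < n_thresholds:
        binaries.append(np.zeros_like(roi.mask))
    # upper-threshold images
    for t in thresholds:
        binaries.append(roi.mask & (roi.intensities > t))
    while len(binaries) < 2 * n_thresholds:
        binaries.append(np.zeros_like(roi.mask))
    return binaries, thresholds


def sfta_features(
    roi: SliceROI,
    n_thresholds: int = 8,
    box_sizes: Sequence[int] = (1, 2, 4, 8),
) -> np.ndarray:
    """The 48 SFTA values: (border FD, mean gray, size) per binary image.

    Band images come first, then upper images, each contributing its triple
    in (FD, mean, size) order.  Images emptied by degenerate thresholds
    contribute (0, 0, 0).
    """
    binaries, _ = sfta_binary_images(roi, n_thresholds)
    out = []
    for fg in binaries:
        size = int(fg.sum())
        if size == 0:
            out.extend([0.0, 0.0, 0.0])
            continue
        fd = box_counting_dimension(_region_borders(fg), box_sizes)
        mean_gray = float(roi.intensities[fg].mean())
        out.extend([fd, mean_gray, float(size)])
    return np.asarray(out)


# ---------------------------------------------------------------------------
# DBC fractal-dimension image
# ---------------------------------------------------------------------------


def dbc_fd_image(
    roi: SliceROI,
    window: int = 7,
    box_sizes: Sequence[int] = (2, 3, 7),
) -> FDImage:
    """Local fractal dimension by differential box counting in a sliding
    window.

    A pixel is valid iff its full window lies in-mask.  Within a window of
    side M, the intensity surface (relative to the window minimum, making
    the estimate shift invariant) is covered with boxes of side s and height
    h = s * G / M, where G is the in-mask gray range of the whole slice; the
    per-box count ceil(max/h) - ceil(min/h) + 1 is averaged over the
    complete s x s blocks and scaled to the window area, and the dimension
    is the slope of log N versus log(1/r), r = s/M.
    """
    M = window
    half = M // 2
    valid = ndimage.binary_erosion(roi.mask, structure=np.ones((M, M), dtype=bool))
    if not valid.any():
        raise DegenerateROIError(f"no pixel has full {M}x{M} in-mask support")
    vals = roi.intensities[roi.mask]
    G = float(vals.max() - vals.min())
    if G <= 0:
        G = 1.0
    img = roi.intensities
    windows = sliding_window_view(img, (M, M))  # (nr-M+1, nc-M+1, M, M)
    vr, vc = np.nonzero(valid)
    W = windows[vr - half, vc - half]  # (nv, M, M)
    W = W - W.min(axis=(1, 2), keepdims=True)

    log_n = []
    log_inv_r = []
    for s in box_sizes:
        h = s * G / M
        nb = M // s
        core = W[:, : nb * s, : nb * s].reshape(W.shape[0], nb, s, nb, s)
        bmax = core.max(axis=(2, 4))
        bmin = core.min(axis=(2, 4))
        contrib = np.ceil(bmax / h) - np.ceil(bmin / h) + 1.0
        n_r = contrib.reshape(W.shape[0], -1).mean(axis=1) * (M / s) ** 2
        log_n.append(np.log(n_r))
        log_inv_r.append(np.log(M / s))
    X = np.asarray(log_inv_r)
    Y = np.stack(log_n, axis=1)  # (nv, n_sizes)
    xm = X.mean()
    slope = ((X - xm) @ Y.T) / ((X - xm) ** 2).sum()

    fd = np.zeros(img.shape)
    fd[vr, vc] = slope
    return FDImage(fd=fd, valid=valid)


def fd_image_stats(fdi: FDImage) -> Tuple[float, float, float]:
    """(mean, std, lacunarity) of the valid local fractal dimensions.

    Lacunarity is the moment form E[X^2]/E[X]^2 - 1 (variance over squared
    mean), the standard gappiness measure; it is 0 for a constant FD image.
    """
    x = fdi.fd[fdi.valid]
    m = float(x.mean())
    sd = float(x.std())
    lac = float(sd**2 / m**2) if m != 0 else 0.0
    return m, sd, lac


def fd2_features(fd_images: Sequence[FDImage]) -> np.ndarray:
    """Max-over-slices and mean-over-slices of the per-slice FD-image
    (mean, std, lacunarity): [max_mean, max_std, max_lac, mean_mean,
    mean_std, mean_lac]."""
    stats = [fd_image_stats(f) for f in fd_images if f.valid.any()]
    if not stats:
        warnings.warn("all slices degenerate for DBC; FD2 features zeroed", stacklevel=2)
        return np.zeros(6)
    arr = np.asarray(stats)  # (n_slices, 3)
    return np.concatenate([arr.max(axis=0), arr.mean(axis=0)])
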