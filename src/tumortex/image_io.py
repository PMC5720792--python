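"""Volume/mask I/O, per-slice tumor ROI extraction, and gray-level quantization.

The unit of analysis is a 3-D intensity volume with an aligned binary tumor
mask.  Texture features are 2-D: each axial slice carrying enough in-mask
pixels is cropped to the mask bounding box and analysed independently, then
averaged at the pipeline level.  Gray levels are quantized per slice into N
equal-width bins spanning the in-mask intensity range of that slice, which
makes every downstream co-occurrence feature invariant to affine intensity
rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import nibabel as nib
import numpy as np

from .errors import AlignmentError, EmptyTumorError, MaskFormatError, ParameterError


@dataclass
class TumorVolume:
    """A 3-D intensity array with an aligned binary mask and voxel spacing."""

    intensities: np.ndarray  # (nx, ny, nz) float
    mask: np.ndarray  # (nx, ny, nz) bool
    spacing: Tuple[float, float, float]
    label: int | None = None
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if self.intensities.shape != self.mask.shape:
            raise AlignmentError(
                f"volume shape {self.intensities.shape} != mask shape {self.mask.shape}"
            )


@dataclass
class SliceROI:
    """One axial tumor cross-section, cropped to the mask bounding box."""

    intensities: np.ndarray  # 2-D float
    mask: np.ndarray  # 2-D bool
    slice_index: int = 0

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class QuantizedROI:
    """Slice ROI with in-mask intensities binned to integer levels 1..N.

    Out-of-mask pixels carry the sentinel level 0.
    """

    levels: np.ndarray  # 2-D int, 0 outside mask
    N: int
    mask: np.ndarray  # 2-D bool


def load_volume_and_mask(volume_path, mask_path) -> TumorVolume:
    """Load an aligned NIfTI volume/mask pair.

    Raises
    ------
    AlignmentError
        If the two images do not have identical array shapes.
    MaskFormatError
        If the mask contains values other than 0 and 1.
    """
    vol_img = nib.load(str(volume_path))
    mask_img = nib.load(str(mask_path))
    vol = np.asarray(vol_img.get_fdata(), dtype=float)
    mask_arr = np.asarray(mask_img.get_fdata())
    if vol.shape != mask_arr.shape:
        raise AlignmentError(
            f"volume shape {vol.shape} does not match mask shape {mask_arr.shape}"
        )
    values = np.unique(mask_arr)
    if not np.all(np.isin(values, (0, 1))):
        raise MaskFormatError(f"mask is not binary; found values {values[:10]}")
    spacing = tuple(float(z) for z in vol_img.header.get_zooms()[:3])
    return TumorVolume(intensities=vol, mask=mask_arr.astype(bool), spacing=spacing)


def extract_slice_rois(tumor: TumorVolume, min_pixels: int = 9) -> List[SliceROI]:
    """Carve one cropped ROI per qualifying axial slice, in slice order.

    A slice qualifies when its mask foreground holds at least ``min_pixels``
    pixels; sub-threshold slices are dropped.  Axial slicing uses the third
    array axis.
    """
    if min_pixels < 1:
        raise ParameterError("min_pixels must be >= 1")
    rois: List[SliceROI] = []
    for z in range(tumor.mask.shape[2]):
        m = tumor.mask[:, :, z]
        if int(m.sum()) < min_pixels:
            continue
        rows = np.flatnonzero(m.any(axis=1))
        cols = np.flatnonzero(m.any(axis=0))
        r0, r1 = rows[0], rows[-1] + 1
        c0, c1 = cols[0], cols[-1] + 1
        rois.append(
            SliceROI(
                intensities=np.ascontiguousarray(
                    tumor.intensities[r0:r1, c0:c1, z], dtype=float
                ),
                mask=np.ascontiguousarray(m[r0:r1, c0:c1]),
                slice_index=z,
            )
        )
    if not rois:
        raise EmptyTumorError(
            f"no axial slice carries >= {min_pixels} in-mask pixels"
        )
    return rois


def quantize_roi(roi: SliceROI, N: int = 16) -> QuantizedROI:
    """Bin in-mask intensities into N equal-width levels labeled 1..N.

    The reference range is the in-mask min/max of this slice; the maximum
    maps to level N.  A constant ROI maps to level 1 everywhere (degenerate
    range convention), keeping downstream matrices well-defined.
    """
    if N < 2:
        raise ParameterError("N must be >= 2")
    vals = roi.intensities[roi.mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(roi.intensities.shape, dtype=np.int64)
    if hi > lo:
        scaled = (roi.intensities - lo) / (hi - lo) * N
        binned = np.minimum(np.floor(scaled).astype(np.int64) + 1, N)
        levels[roi.mask] = binned[roi.mask]
    else:
        levels[roi.mask] = 1
    return QuantizedROI(levels=levels, N=N, mask=roi.mask)
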