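"""Feature-extraction configuration.

All knobs of the texture pipeline live here so that a feature vector can be
reproduced from its provenance snapshot alone.  Defaults follow the published
operating point of the method: co-occurrence distance ``d = 2`` pixels at
``N = 16`` gray levels, Renyi order ``q = 8``, Tsallis order ``r = 2``, angle
co-occurrence displacement ``l = 1`` with ``n_theta = 8`` orientation bins,
and the four-direction set {0, 45, 90, 135} degrees for rotation-invariant
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the 255-feature extraction.

    Attributes
    ----------
    d : int
        Pixel displacement for the gray-level co-occurrence matrix.
    N : int
        Number of quantized gray levels (ROI-relative, per slice).
    q, r : float
        Orders of the Renyi and Tsallis entropies (G18/G19 and their ACM
        analogues).
    l : int
        Pixel displacement for the angle co-occurrence matrices.
    n_theta : int
        Number of quantized gradient-orientation bins over [0, 360).
    angles : tuple of int
        Displacement directions (degrees) averaged for rotation invariance.
    min_pixels : int
        Minimum in-mask pixel count for a slice to enter the analysis; the
        default 9 guarantees a 3x3 operator footprint can fit.
    ih_bins : int
        Bin count of the intensity histogram used for the first-order
        entropy feature (matches the gray-level depth N).
    n_thresholds : int
        Number of multi-level Otsu thresholds in the SFTA decomposition
        (yields 2 * n_thresholds binary images).
    dbc_window : int
        Side of the sliding window of the differential box-counting
        fractal-dimension image (odd).
    dbc_box_sizes : tuple of int
        Box sizes used inside each DBC window.
    border_box_sizes : tuple of int
        Dyadic box sizes for the SFTA border box-counting dimension.
    tsallis_conventional : bool
        If True, use the conventional Tsallis form (1 - sum p^r)/(r - 1)
        instead of the printed form (1/(1-r)) * sum p^r.  Default False:
        the printed form is reproduced as-is.
    area_weighted_slices : bool
        If True, weight the per-slice feature average by in-mask area.
        Default False: plain arithmetic mean over qualifying slices.
    """

    d: int = 2
    N: int = 16
    q: float = 8.0
    r: float = 2.0
    l: int = 1
    n_theta: int = 8
    angles: Tuple[int, ...] = (0, 45, 90, 135)
    min_pixels: int = 9
    ih_bins: int = 16
    n_thresholds: int = 8
    dbc_window: int = 7
    dbc_box_sizes: Tuple[int, ...] = (2, 3, 7)
    border_box_sizes: Tuple[int, ...] = (1, 2, 4, 8)
    tsallis_conventional: bool = False
    area_weighted_slices: bool = False

    def snapshot(self) -> dict:
        """JSON-serialisable provenance snapshot of every parameter."""
        return asdict(self)


DEFAULT_CONFIG = FeatureConfig()
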