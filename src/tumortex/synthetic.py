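"""Synthetic labeled tumor volumes and deterministic micro-fixtures.

Clinical CT cohorts for this problem are not publicly deposited, so the
package ships a generator that emulates the *structure* of the study data:
ellipsoidal tumors of roughly 1-20 cm^3 on a pseudo-Hounsfield intensity
scale, spanning a homogeneous-to-heterogeneous texture continuum, with a
binary label encoding 2-year survival (the study cohort is 20 short
survivors vs 15 long survivors).

The two texture regimes encode the radiological observation that poor
prognosis associates with heterogeneous, edge-rich tumors:

* label 0 (survival < 2 years): an oriented band-limited pattern with a
  per-tumor random dominant direction plus 1-3 hypointense necrosis-like
  blobs -- strong, directionally coherent gradients;
* label 1 (survival >= 2 years): an isotropic low-frequency smooth field
  of matched marginal variance -- weak, incoherent gradients.

The ``texture_effect`` dial in [0, 1] scales both regime components, so at
0 the two classes are drawn from exactly the same distribution (null
calibration) and class separation grows monotonically with the dial.  The
generator makes no claim about PDAC biology or CT physics; it provides a
controlled ground truth for pipeline testing.

Everything is driven by numpy SeedSequence streams hashed from
(cohort seed, patient index), so cohorts are bit-reproducible and stable
under partial regeneration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError
from .image_io import SliceROI, TumorVolume

DEFAULT_SPACING = (0.7324, 0.7324, 2.5)  # mm; matches the study voxel size

BASE_HU = 70.0  # center of the portal-venous soft-tissue band [20, 120]
TEXTURE_SD = 16.0  # marginal sd of the regime component at effect 1
SMOOTH_SD = 5.0  # sd of the shared low-frequency background field
BLOB_DEPTH = 35.0  # peak hypointensity of necrosis-like blobs at effect 1


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a labeled synthetic cohort.

    Defaults reproduce the study's cohort structure (20 short / 15 long
    survivors) at a reduced in-plane matrix that keeps full-pipeline runs
    fast while leaving every texture operator well-supported.
    """

    n_short_survivors: int = 20
    n_long_survivors: int = 15
    volume_shape: Tuple[int, int, int] = (32, 32, 8)
    slice_count_range: Tuple[int, int] = (3, 6)
    texture_effect: float = 1.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_short_survivors < 1 or self.n_long_survivors < 1:
            raise ParameterError("each class needs at least one tumor")
        if not (0.0 <= self.texture_effect <= 1.0):
            raise ParameterError("texture_effect must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class LabeledTumorVolume(TumorVolume):
    """TumorVolume whose label/patient_id are mandatory in practice."""


def _unit_sd(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return x / sd if sd > 0 else x


def _bandpass_field(
    rng: np.random.Generator,
    shape: Tuple[int, int, int],
    f_center: float,
    bandwidth: float = 0.35,
    orientation: float | None = None,
    ang_sigma: float = 0.25,
) -> np.ndarray:
    """Unit-variance band-pass noise, optionally orientation-coherent.

    White noise is filtered per axial slice in the Fourier domain with a
    Gaussian annulus centered at radial frequency ``f_center`` (cycles per
    pixel, relative width ``bandwidth``).  With ``orientation`` set, the
    annulus is additionally windowed to a symmetric angular wedge of width
    ``ang_sigma`` radians around that direction, producing texture whose
    gradients share a dominant orientation without changing the marginal
    intensity distribution.
    """
    noise = rng.standard_normal(shape)
    fx = np.fft.fftfreq(shape[0])[:, None]
    fy = np.fft.fftfreq(shape[1])[None, :]
    rho = np.hypot(fx, fy)
    H = np.exp(-0.5 * ((rho - f_center) / (bandwidth * f_center)) ** 2)
    H[0, 0] = 0.0
    if orientation is not None:
        theta = np.arctan2(fy, fx)
        delta = np.angle(np.exp(2j * (theta - orientation))) / 2.0  # mod pi
        H = H * np.exp(-0.5 * (delta / ang_sigma) ** 2)
    spec = np.fft.fft2(noise, axes=(0, 1)) * H[..., None]
    field = np.real(np.fft.ifft2(spec, axes=(0, 1)))
    return _unit_sd(field)


def generate_tumor(
    label: int,
    axes_mm: Sequence[float] = (14.0, 14.0, 10.0),
    texture_effect: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    volume_shape: Tuple[int, int, int] = (32, 32, 8),
    spacing: Tuple[float, float, float] = DEFAULT_SPACING,
    noise_sd: float = 2.0,
    patient_id: str | None = None,
) -> LabeledTumorVolume:
    """Generate one ellipsoidal tumor volume with a label-specific texture.

    ``axes_mm`` are the full ellipsoid axes in millimetres.  The random
    stream is consumed in a label-independent order for the shared
    components, so at ``texture_effect = 0`` the two labels produce
    *identical* volumes for the same seed (exchangeable classes).
    """
    axes = np.asarray(axes_mm, dtype=float)
    if np.any(axes <= 0):
        raise ParameterError("ellipsoid axes must be positive")
    if not (0.0 <= texture_effect <= 1.0):
        raise ParameterError("texture_effect must lie in [0, 1]")
    if label not in (0, 1):
        raise ParameterError("label must be 0 or 1")
    rng = np.random.default_rng(seed)
    shape = tuple(volume_shape)
    semi_vox = axes / 2.0 / np.asarray(spacing)

    center = (np.asarray(shape) - 1) / 2.0 + rng.uniform(-0.5, 0.5, size=3)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    q = sum(((g - c) / sv) ** 2 for g, c, sv in zip(grids, center, semi_vox))
    mask = q <= 1.0
    slice_counts = mask.any(axis=(0, 1)).sum()
    if mask.sum() == 0 or slice_counts < 2:
        raise ParameterError(
            "ellipsoid axes too small for the voxel grid: mask must cover "
            ">= 2 axial slices"
        )

    # shared components (drawn first, identically for both labels)
    base = SMOOTH_SD * _unit_sd(
        ndimage.gaussian_filter(rng.standard_normal(shape), sigma=(3.0, 3.0, 1.0))
    )
    white = rng.normal(0.0, noise_sd, size=shape) if noise_sd > 0 else 0.0

    # label-specific heterogeneity, scaled by texture_effect.  Both regimes
    # are band-pass noise fields normalized to the same marginal variance,
    # so first-order intensity statistics are closely matched and the
    # dominant class contrast is *directional*: label 0 concentrates its
    # spectral power in a random orientation wedge (plus necrosis-like
    # blobs), label 1 spreads it isotropically at a lower frequency.
    t = float(texture_effect)
    if label == 0:
        phi = rng.uniform(0.0, np.pi)
        wavelength = rng.uniform(3.5, 5.5)
        field = _bandpass_field(
            rng, shape, f_center=1.0 / wavelength, orientation=phi, ang_sigma=0.25
        )
        regime = TEXTURE_SD * field
        n_blobs = int(rng.integers(1, 4))
        blob = np.zeros(shape)
        for _ in range(n_blobs):
            bc = center + rng.uniform(-0.5, 0.5, size=3) * semi_vox
            bs = np.array([rng.uniform(1.5, 3.0), rng.uniform(1.5, 3.0), 1.0])
            d2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, bc, bs))
            blob -= BLOB_DEPTH * np.exp(-0.5 * d2)
        regime = regime + blob
    else:
        wavelength = rng.uniform(7.0, 10.0)
        field = _bandpass_field(rng, shape, f_center=1.0 / wavelength)
        regime = TEXTURE_SD * field

    intensities = BASE_HU + base + t * regime + white
    return LabeledTumorVolume(
        intensities=intensities,
        mask=mask,
        spacing=tuple(spacing),
        label=int(label),
        patient_id=patient_id,
    )


def generate_cohort(spec: SyntheticCohortSpec) -> List[LabeledTumorVolume]:
    """Generate the full labeled cohort described by ``spec``.

    Tumors are ordered short survivors (label 0) first, then long
    survivors.  Each tumor's RNG stream is hashed from
    (spec.seed, patient index), so regenerating a subset reproduces the
    same volumes.
    """
    nx, ny, nz = spec.volume_shape
    smin, smax = spec.slice_count_range
    if smax > nz:
        raise ParameterError("slice_count_range exceeds volume depth")
    labels = [0] * spec.n_short_survivors + [1] * spec.n_long_survivors
    sx, sy, sz = DEFAULT_SPACING
    volumes: List[LabeledTumorVolume] = []
    for idx, label in enumerate(labels):
        ss = np.random.SeedSequence((spec.seed, idx))
        geom = np.random.default_rng(np.random.SeedSequence((spec.seed, idx, 1)))
        # in-plane diameter: 55-80% of the matrix; depth per slice budget
        dx = geom.uniform(0.55, 0.80) * nx * sx
        dy = geom.uniform(0.55, 0.80) * ny * sy
        n_slices = int(geom.integers(smin, smax + 1))
        dz = (n_slices + 0.6) * sz
        volumes.append(
            generate_tumor(
                label=label,
                axes_mm=(dx, dy, dz),
                texture_effect=spec.texture_effect,
                seed=ss,
                volume_shape=spec.volume_shape,
                noise_sd=spec.noise_sd,
                patient_id=f"P{idx:03d}",
            )
        )
    return volumes


def write_cohort(
    volumes: Sequence[LabeledTumorVolume], out_dir
) -> pd.DataFrame:
    """Write volumes/masks as NIfTI pairs plus a cohort manifest CSV.

    Returns the manifest (patient_id, label, volume/mask paths).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for vol in volumes:
        affine = np.diag(list(vol.spacing) + [1.0])
        vpath = out / f"{vol.patient_id}_volume.nii.gz"
        mpath = out / f"{vol.patient_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(vol.intensities.astype(np.float64), affine), vpath)
        nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), affine), mpath)
        rows.append(
            {
                "patient_id": vol.patient_id,
                "label": int(vol.label),
                "volume_path": str(vpath),
                "mask_path": str(mpath),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def planted_feature_table(
    seed: int,
    n_short: int = 20,
    n_long: int = 15,
    n_features: int = 50,
    planted: Tuple[int, int] = (7, 23),
    noise_sd: float = 0.1,
    n_blind: int = 3,
):
    """A numeric feature table with exactly two complementary informative
    columns, for testing selection-size recovery.

    Each planted column tracks the class label except on its own disjoint
    trio of short survivors, where its value is *flipped* to the long-
    survivor level; the partner column is clean there.  Alone, either
    column therefore misclassifies its blind trio; together they separate
    the classes perfectly, so the optimal forward-selection size is exactly
    two.  All other columns are standard-normal noise.

    Returns (X, y, planted_indices).
    """
    rng = np.random.default_rng(seed)
    n = n_short + n_long
    y = np.concatenate([np.zeros(n_short, dtype=int), np.ones(n_long, dtype=int)])
    X = rng.normal(size=(n, n_features))
    ia, ib = planted
    fa = y + rng.normal(0.0, noise_sd, n)
    fb = y + rng.normal(0.0, noise_sd, n)
    blind_a = rng.choice(np.flatnonzero(y == 0), n_blind, replace=False)
    rest = np.setdiff1d(np.flatnonzero(y == 0), blind_a)
    blind_b = rng.choice(rest, n_blind, replace=False)
    fa[blind_a] = 1.0 + rng.normal(0.0, 0.02, n_blind)
    fb[blind_b] = 1.0 + rng.normal(0.0, 0.02, n_blind)
    X[:, ia] = fa
    X[:, ib] = fb
    return X, y, (ia, ib)


def fixture_rois() -> Dict[str, SliceROI]:
    """Tiny deterministic 2-D ROIs used as oracle targets in unit tests.

    * ``constant8`` -- 8x8 single value, full mask;
    * ``checker``   -- 8x8 two-level period-1 checkerboard;
    * ``rampx``     -- 8x8 intensity strictly increasing left to right;
    * ``rampxy``    -- left half a column ramp, right half a row ramp;
    * ``quant4``    -- 4x4 with in-mask values {0, 5, 10, 15};
    * ``lmask``     -- 6x6 ramp under an L-shaped mask (runs break at the
      mask hole).
    """
    full8 = np.ones((8, 8), dtype=bool)
    rois: Dict[str, SliceROI] = {}
    rois["constant8"] = SliceROI(np.full((8, 8), 50.0), full8.copy())
    rr, cc = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
    rois["checker"] = SliceROI(np.where((rr + cc) % 2 == 0, 10.0, 20.0), full8.copy())
    rois["rampx"] = SliceROI((cc * 10.0).astype(float), full8.copy())
    composite = np.where(cc < 4, cc * 10.0, rr * 10.0)
    rois["rampxy"] = SliceROI(composite.astype(float), full8.copy())
    vals4 = np.tile(np.array([0.0, 5.0, 10.0, 15.0]), (4, 1))
    rois["quant4"] = SliceROI(vals4, np.ones((4, 4), dtype=bool))
    lm = np.ones((6, 6), dtype=bool)
    lm[:3, 3:] = False
    r6, c6 = np.meshgrid(np.arange(6), np.arange(6), indexing="ij")
    rois["lmask"] = SliceROI((r6 * 6.0 + c6).astype(float), lm)
    return rois
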