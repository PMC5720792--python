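"""Per-tumor feature extraction and cohort table assembly.

A tumor is described by an ordered, named vector of 255 texture features:

====== ======= =====================================================
block  length  content
====== ======= =====================================================
G1-19      19  GLCM statistics (Haralick 14 + inertia, cluster shade,
               cluster prominence, Renyi, Tsallis)
R1-11      11  run-length features, four-direction averaged
L1-128    128  LBP block (ULBP, RI-ULBP, histogram stats, LBP-HF)
F1_1-48    48  SFTA triples (border FD, mean gray, size) x 16 images
F2_1-6      6  DBC fractal-dimension image statistics
I1-5        5  intensity-histogram first-order statistics
A1-19      19  ACM1 (gradient-orientation co-occurrence) statistics
M1-19      19  ACM2 (magnitude-weighted) statistics
====== ======= =====================================================

All blocks except F2 are computed per qualifying slice and arithmetically
averaged over slices; F2 applies its own max/mean aggregation to per-slice
FD-image statistics.  The feature registry reconstructs the published
ordering from the per-family counts; it is versioned by the config
snapshot embedded in each vector's provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, FeatureConfig
from .cooccur import (
    STAT_NAMES,
    RLM_FEATURE_NAMES,
    acm_feature_block,
    compute_glcm,
    cooccurrence_stats19,
    rlm_features,
)
from .errors import CohortError, DegenerateROIError, EmptyTumorError
from .fractal import dbc_fd_image, fd2_features, sfta_features
from .image_io import TumorVolume, extract_slice_rois, quantize_roi
from .local_patterns import intensity_histogram_features, lbp_feature_block

FAMILY_PREFIXES = {
    "glcm": "glcm.",
    "rlm": "rlm.",
    "lbp": "lbp.",
    "fd1": "sfta.",
    "fd2": "fd2.",
    "ih": "ih.",
    "acm1": "acm1.",
    "acm2": "acm2.",
}

_SHORT_STATS = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "diff_variance",
    "diff_entropy",
    "imc1",
    "imc2",
    "mcc",
    "inertia",
    "cluster_shade",
    "cluster_prominence",
    "renyi",
    "tsallis",
)

_SHORT_RLM = (
    "sre",
    "lre",
    "gln",
    "rln",
    "rp",
    "lgre",
    "hgre",
    "srlge",
    "srhge",
    "lrlge",
    "lrhge",
)

_LBP_STAT_HISTS = ("lbp256", "ulbp", "riulbp", "rilbp36", "rotlbp")
_LBP_STAT_NAMES = ("std", "skewness", "kurtosis", "entropy")


@lru_cache(maxsize=1)
def feature_names() -> Tuple[str, ...]:
    """The ordered registry of all 255 feature names.

    Names encode family and published index, e.g. ``glcm.G18_renyi`` or
    ``acm2.M11_diff_entropy``, so the indices quoted in downstream analyses
    resolve unambiguously.
    """
    names: List[str] = []
    names += [f"glcm.G{i+1}_{s}" for i, s in enumerate(_SHORT_STATS)]
    names += [f"rlm.R{i+1}_{s}" for i, s in enumerate(_SHORT_RLM)]
    lbp: List[str] = []
    lbp += [f"ulbp_bin{k+1}" for k in range(58)] + ["ulbp_nonuniform"]
    lbp += [f"riulbp_ones{k}" for k in range(9)] + ["riulbp_nonuniform"]
    for h in _LBP_STAT_HISTS:
        lbp += [f"{h}_{s}" for s in _LBP_STAT_NAMES]
    lbp += ["hf_spectrum_entropy"]
    lbp += [f"hf_n{n}_u{u}" for n in range(1, 8) for u in range(5)]
    lbp += ["hf_all_zeros", "hf_all_ones", "hf_nonuniform"]
    assert len(lbp) == 128
    names += [f"lbp.L{i+1}_{s}" for i, s in enumerate(lbp)]
    sfta: List[str] = []
    for img in [f"band{k+1}" for k in range(8)] + [f"upper{k+1}" for k in range(8)]:
        sfta += [f"{img}_fd", f"{img}_mean", f"{img}_size"]
    names += [f"sfta.F1_{i+1}_{s}" for i, s in enumerate(sfta)]
    fd2 = ["max_mean", "max_std", "max_lacunarity", "mean_mean", "mean_std", "mean_lacunarity"]
    names += [f"fd2.F2_{i+1}_{s}" for i, s in enumerate(fd2)]
    ih = ["mean", "std", "skewness", "kurtosis", "entropy"]
    names += [f"ih.I{i+1}_{s}" for i, s in enumerate(ih)]
    names += [f"acm1.A{i+1}_{s}" for i, s in enumerate(_SHORT_STATS)]
    names += [f"acm2.M{i+1}_{s}" for i, s in enumerate(_SHORT_STATS)]
    assert len(names) == 255
    return tuple(names)


def family_columns(family: str) -> List[str]:
    """Registry names belonging to one feature family (or 'all')."""
    if family == "all":
        return list(feature_names())
    try:
        prefix = FAMILY_PREFIXES[family]
    except KeyError:
        raise ValueError(f"unknown family {family!r}; choose from "
                         f"{sorted(FAMILY_PREFIXES)} or 'all'") from None
    return [n for n in feature_names() if n.startswith(prefix)]


@dataclass
class FeatureVector:
    """A named 255-element tumor descriptor with its config provenance."""

    values: np.ndarray
    names: Tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


@dataclass
class CohortTable:
    """n_patients x 255 feature matrix with binary survival labels."""

    features: pd.DataFrame  # columns = feature names, index = patient ids
    labels: np.ndarray  # 1 = survival >= 2 years
    patient_ids: List[str]

    @property
    def n(self) -> int:
        return len(self.patient_ids)


def _slice_features_249(roi, config: FeatureConfig) -> np.ndarray:
    """All per-slice-averaged blocks (everything except FD2) for one ROI."""
    qroi = quantize_roi(roi, config.N)
    g = cooccurrence_stats19(
        compute_glcm(qroi, d=config.d, angles=config.angles),
        q=config.q,
        r=config.r,
        tsallis_conventional=config.tsallis_conventional,
    )
    rl = rlm_features(qroi, angles=config.angles)
    lb = lbp_feature_block(roi).values
    f1 = sfta_features(roi, n_thresholds=config.n_thresholds,
                       box_sizes=config.border_box_sizes)
    ih = intensity_histogram_features(roi, n_bins=config.ih_bins)
    am = acm_feature_block(
        roi,
        l=config.l,
        n_theta=config.n_theta,
        q=config.q,
        r=config.r,
        angles=config.angles,
        tsallis_conventional=config.tsallis_conventional,
    )
    return np.concatenate([g, rl, lb, f1, ih, am])


def extract_tumor_features(
    tumor: TumorVolume, config: FeatureConfig = DEFAULT_CONFIG
) -> FeatureVector:
    """Extract the full 255-element feature vector of one tumor.

    Per-slice features are averaged over all qualifying slices (unweighted
    by default; in-mask-area weighting behind a config flag).  FD2 follows
    its own max/mean rule over per-slice FD-image statistics.  Non-finite
    values are zero-filled with a warning so cohort tables stay complete.
    """
    rois = extract_slice_rois(tumor, min_pixels=config.min_pixels)
    per_slice = []
    weights = []
    fd_images = []
    for roi in rois:
        try:
            feats = _slice_features_249(roi, config)
        except DegenerateROIError:
            # e.g. an end slice with >= min_pixels scattered pixels but no
            # full 3x3 interior; such slices cannot support the gradient
            # and pattern operators and are dropped like sub-threshold ones
            warnings.warn(
                f"slice {roi.slice_index} lacks interior support; skipped",
                stacklevel=2,
            )
            continue
        per_slice.append(feats)
        weights.append(roi.n_pixels)
        try:
            fd_images.append(dbc_fd_image(roi, window=config.dbc_window,
                                          box_sizes=config.dbc_box_sizes))
        except DegenerateROIError:
            pass
    if not per_slice:
        raise EmptyTumorError("no slice supports the 3x3 texture operators")
    mat = np.asarray(per_slice)
    if config.area_weighted_slices:
        w = np.asarray(weights, dtype=float)
        avg = (mat * w[:, None]).sum(axis=0) / w.sum()
    else:
        avg = mat.mean(axis=0)
    if fd_images:
        f2 = fd2_features(fd_images)
    else:
        warnings.warn("no slice admits the DBC window; FD2 features zeroed",
                      stacklevel=2)
        f2 = np.zeros(6)
    # ordering: G, R, L, F1 | F2 | I, A, M
    values = np.concatenate([avg[:206], f2, avg[206:]])
    bad = ~np.isfinite(values)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} non-finite feature value(s) zero-filled", stacklevel=2
        )
        values[bad] = 0.0
    return FeatureVector(values=values, names=feature_names(),
                         provenance=config.snapshot())


def build_cohort_table(
    volumes: Sequence[TumorVolume], config: FeatureConfig = DEFAULT_CONFIG
) -> CohortTable:
    """Feature table for a labeled cohort, rows in input order."""
    if len(volumes) < 2:
        raise CohortError("need at least 2 patients")
    labels = np.array([int(v.label) for v in volumes])
    if len(np.unique(labels)) < 2:
        raise CohortError("cohort must contain both survival classes")
    rows = []
    ids = []
    for k, vol in enumerate(volumes):
        fv = extract_tumor_features(vol, config)
        rows.append(fv.values)
        ids.append(vol.patient_id if vol.patient_id is not None else f"P{k:03d}")
    features = pd.DataFrame(np.asarray(rows), index=ids, columns=list(feature_names()))
    return CohortTable(features=features, labels=labels, patient_ids=ids)
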