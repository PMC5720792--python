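"""Fuzzy minimum-redundancy maximum-relevance (fMRMR) feature selection.

Each continuous feature is fuzzified into a small triangular partition of
unity whose set centers sit at fixed quantiles of the training data (10th /
50th / 90th percentile for the default 3 sets).  Mutual information between
two fuzzified variables is computed from the fuzzy joint frequency matrix
p(i, j) = (1/n) * sum_s a_si * b_sj with base-2 logs.  Because memberships
depend only on a feature's quantiles, the ranking is invariant to strictly
monotone transforms of individual features.

Ranking is incremental: the m-th feature maximizes

    J(f_j) = MI(f_j; c) - (1/(m-1)) * sum_{f_i selected} MI(f_j; f_i)

(the redundancy term is empty at m = 1, so the first feature is simply the
most class-relevant one).  The class vector is fuzzified as crisp two-set
membership.  Ties break toward the lowest feature index.

Forward selection then picks the optimal subset size O as the smallest k
minimizing the leave-one-out misclassification rate of a Gaussian
naive-Bayes classifier on the first k ranked features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .errors import AlignmentError, CohortError


@dataclass
class FuzzyPartition:
    """Row-stochastic membership matrix of one variable."""

    membership: np.ndarray  # (n_samples, n_sets)
    set_centers: np.ndarray


@dataclass
class RankedFeatures:
    """Feature indices in descending fMRMR importance with criterion values."""

    order: np.ndarray  # permutation of 0..D-1
    criteria: np.ndarray  # J value at each selection step


@dataclass
class SelectionResult:
    O: int
    subset: np.ndarray  # the first O ranked indices
    error_trace: np.ndarray  # e_k for k = 1..k_max


def fuzzify(x: np.ndarray, n_sets: int = 3) -> FuzzyPartition:
    """Triangular partition-of-unity memberships with quantile centers.

    Memberships are computed on the empirical rank scale: each sample's
    normalized average rank u in [0, 1] is interpolated linearly between
    set centers placed at equally spaced quantile levels from the 10th to
    the 90th percentile.  Samples at or beyond the outer centers belong
    fully to the outer sets.  Because average ranks are preserved by any
    strictly monotone transform, so is the whole partition -- which is what
    makes the downstream ranking scale-free.  A constant variable collapses
    to full membership in set 1.
    """
    from scipy.stats import rankdata

    x = np.asarray(x, dtype=float)
    if n_sets < 2:
        raise ValueError("n_sets must be >= 2")
    qs = np.linspace(0.10, 0.90, n_sets)
    centers = np.quantile(x, qs)
    m = np.zeros((x.size, n_sets))
    if np.unique(x).size < 2 or x.size < 2:
        m[:, 0] = 1.0
        return FuzzyPartition(membership=m, set_centers=centers)
    u = (rankdata(x, method="average") - 1.0) / (x.size - 1.0)
    idx = np.clip(np.searchsorted(qs, u, side="right") - 1, 0, n_sets - 2)
    t = np.clip((u - qs[idx]) / (qs[idx + 1] - qs[idx]), 0.0, 1.0)
    t[u <= qs[0]] = 0.0
    t[u >= qs[-1]] = 1.0
    idx[u >= qs[-1]] = n_sets - 2
    rows = np.arange(x.size)
    np.add.at(m, (rows, idx), 1.0 - t)
    np.add.at(m, (rows, idx + 1), t)
    return FuzzyPartition(membership=m, set_centers=centers)


def crisp_partition(labels: np.ndarray) -> FuzzyPartition:
    """One-hot (crisp) membership for a binary class vector."""
    labels = np.asarray(labels, dtype=int)
    m = np.zeros((labels.size, 2))
    m[np.arange(labels.size), labels] = 1.0
    return FuzzyPartition(membership=m, set_centers=np.array([0.0, 1.0]))


def _mi_from_joint(p: np.ndarray) -> float:
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    outer = px * py
    pos = (p > 0) & (outer > 0)
    mi = float((p[pos] * np.log2(p[pos] / outer[pos])).sum())
    return max(mi, 0.0)


def fuzzy_mutual_information(a: FuzzyPartition, b: FuzzyPartition) -> float:
    """Symmetric, nonnegative MI of two fuzzified variables (bits)."""
    if a.membership.shape[0] != b.membership.shape[0]:
        raise AlignmentError("partitions have different sample counts")
    n = a.membership.shape[0]
    joint = a.membership.T @ b.membership / n
    return _mi_from_joint(joint)


def _pairwise_mi(a: np.ndarray, stack: np.ndarray) -> np.ndarray:
    """MI between one membership matrix and a stack of them, vectorized."""
    n = a.shape[0]
    joints = np.einsum("nk,dnl->dkl", a, stack) / n
    px = joints.sum(axis=2, keepdims=True)
    py = joints.sum(axis=1, keepdims=True)
    outer = px * py
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            (joints > 0) & (outer > 0), joints * np.log2(joints / outer), 0.0
        )
    return np.maximum(terms.sum(axis=(1, 2)), 0.0)


def fmrmr_rank(
    X: np.ndarray, y: np.ndarray, n_sets: int = 3
) -> RankedFeatures:
    """Incremental fMRMR ranking of all feature columns of X.

    Parameters
    ----------
    X : (n_samples, n_features) array
        Training feature matrix.  Only training rows may be passed here;
        the cross-validation drivers guarantee held-out data never reaches
        this function.
    y : (n_samples,) binary labels.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, D = X.shape
    if D < 2:
        raise ValueError("need at least 2 features to rank")
    if np.unique(y).size < 2:
        raise CohortError("both classes must be present for ranking")
    memberships = np.stack([fuzzify(X[:, j], n_sets).membership for j in range(D)])
    cls = crisp_partition(y).membership
    relevance = _pairwise_mi(cls, memberships)

    order: List[int] = []
    criteria: List[float] = []
    remaining = np.arange(D)
    red_sum = np.zeros(D)
    for m in range(1, D + 1):
        if m == 1:
            J = relevance[remaining]
        else:
            J = relevance[remaining] - red_sum[remaining] / (m - 1)
        best = int(remaining[np.argmax(J)])  # argmax ties -> lowest index
        order.append(best)
        criteria.append(float(np.max(J)))
        remaining = remaining[remaining != best]
        if remaining.size:
            red_sum[remaining] += _pairwise_mi(
                memberships[best], memberships[remaining]
            )
    return RankedFeatures(order=np.asarray(order), criteria=np.asarray(criteria))


def loo_error_nb(X: np.ndarray, y: np.ndarray, threshold: float = 0.5) -> float:
    """Leave-one-out misclassification rate of the Gaussian NB classifier.

    Implemented with exact leave-one-out updates of the per-class moments,
    so the n refits cost O(n * d) in total.
    """
    from .modeling import _loo_scores_nb  # local import to avoid a cycle

    scores = _loo_scores_nb(X, y)
    pred = (scores >= threshold).astype(int)
    return float((pred != y).mean())


def forward_select(
    ranked: RankedFeatures,
    X: np.ndarray,
    y: np.ndarray,
    k_max: Optional[int] = None,
) -> SelectionResult:
    """Pick the smallest prefix of the ranking minimizing LOO NB error.

    ``k_max`` defaults to min(D, n - 2) so each training fold of the
    internal leave-one-out keeps the naive-Bayes variance estimates defined.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, D = X.shape
    if k_max is None:
        k_max = min(D, n - 2)
    k_max = int(min(k_max, D))
    errors = np.empty(k_max)
    for k in range(1, k_max + 1):
        cols = ranked.order[:k]
        errors[k - 1] = loo_error_nb(X[:, cols], y)
    O = int(np.argmin(errors)) + 1  # first k attaining the minimum
    return SelectionResult(O=O, subset=ranked.order[:O].copy(), error_trace=errors)
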