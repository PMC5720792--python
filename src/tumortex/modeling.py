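"""Gaussian naive-Bayes classification and the two cross-validation
protocols of the survival study, with feature selection nested inside every
training fold.

The classifier models each feature within each class as an independent
Gaussian with equal class priors; posteriors are computed in the log
domain and thresholded at 0.5.  Per-class variances are floored at
1e-9 times the pooled feature variance so post-selection degenerate
features cannot produce infinite likelihoods.  The positive class (label 1)
is survival >= 2 years; sensitivity is the recall of that class and
specificity the recall of the short-survival class.

Two evaluation protocols are provided: leave-one-image-out (one patient
held out per fold) and stratified k-fold cross-validation repeated with
fresh random partitions, with per-repeat metrics averaged over folds and
then over repeats.  In both, the fuzzy-MRMR ranking and forward selection
see only the training rows of each fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import CohortError, FitError, MetricUndefinedError
from .pipeline import CohortTable, family_columns
from .selection import RankedFeatures, SelectionResult, fmrmr_rank, forward_select

_VAR_FLOOR_REL = 1e-9


@dataclass
class GaussianNBModel:
    """Per-class Gaussian moments of the selected features."""

    theta: np.ndarray  # (2, d) class means
    var: np.ndarray  # (2, d) floored class variances
    priors: np.ndarray  # (2,)
    feature_idx: Optional[np.ndarray] = None  # columns used, for bookkeeping


def fit_gaussian_nb(
    X: np.ndarray, y: np.ndarray, priors: Tuple[float, float] = (0.5, 0.5)
) -> GaussianNBModel:
    """Fit per-class means/variances with a relative variance floor."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise FitError("training data contains a single class")
    theta = np.empty((2, X.shape[1]))
    var = np.empty((2, X.shape[1]))
    for c in (0, 1):
        Xc = X[y == c]
        if Xc.shape[0] < 2:
            raise FitError(f"class {c} has fewer than 2 samples")
        theta[c] = Xc.mean(axis=0)
        var[c] = Xc.var(axis=0)
    floor = _VAR_FLOOR_REL * X.var(axis=0) + 1e-12
    var = np.maximum(var, floor)
    p = np.asarray(priors, dtype=float)
    return GaussianNBModel(theta=theta, var=var, priors=p / p.sum())


def predict_posterior(model: GaussianNBModel, X: np.ndarray) -> np.ndarray:
    """Posterior probability of the positive class, computed in log domain."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    logp = np.empty((X.shape[0], 2))
    for c in (0, 1):
        z = (X - model.theta[c]) ** 2 / model.var[c]
        logp[:, c] = (
            -0.5 * (z + np.log(2.0 * np.pi * model.var[c])).sum(axis=1)
            + np.log(model.priors[c])
        )
    m = logp.max(axis=1, keepdims=True)
    w = np.exp(logp - m)
    return w[:, 1] / w.sum(axis=1)


def _loo_scores_nb(
    X: np.ndarray, y: np.ndarray, priors: Tuple[float, float] = (0.5, 0.5)
) -> np.ndarray:
    """Leave-one-out positive-class posteriors via exact moment downdates.

    For the held-out sample i of class c, the class-c mean and variance are
    recomputed from the remaining n_c - 1 samples in closed form; the other
    class is untouched.  Equivalent to n separate fits, in O(n * d).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    n, d = X.shape
    floor = _VAR_FLOOR_REL * X.var(axis=0) + 1e-12
    stats = {}
    for c in (0, 1):
        Xc = X[y == c]
        stats[c] = (Xc.shape[0], Xc.sum(axis=0), (Xc**2).sum(axis=0))
    p = np.asarray(priors, dtype=float)
    p = p / p.sum()
    scores = np.empty(n)
    theta = np.empty((2, d))
    var = np.empty((2, d))
    for i in range(n):
        ci = int(y[i])
        for c in (0, 1):
            nc, s, sq = stats[c]
            if c == ci:
                nc -= 1
                s = s - X[i]
                sq = sq - X[i] ** 2
            theta[c] = s / nc
            var[c] = sq / nc - theta[c] ** 2
        v = np.maximum(var, floor)
        logp = np.empty(2)
        for c in (0, 1):
            z = (X[i] - theta[c]) ** 2 / v[c]
            logp[c] = -0.5 * (z + np.log(2.0 * np.pi * v[c])).sum() + np.log(p[c])
        m = logp.max()
        w = np.exp(logp - m)
        scores[i] = w[1] / w.sum()
    return scores


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> Tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) at a posterior threshold.

    Ties at the threshold classify positive.  Sensitivity is the recall of
    label 1 (survival >= 2 years), specificity the recall of label 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size != labels.size:
        raise MetricUndefinedError("scores and labels differ in length")
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise MetricUndefinedError("both classes required for Sn/Sp")
    pred = (scores >= threshold).astype(int)
    acc = float((pred == labels).mean())
    sn = float((pred[labels == 1] == 1).mean())
    sp = float((pred[labels == 0] == 0).mean())
    return acc, sn, sp


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal AUC; equals the rank statistic with ties counted 1/2."""
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise MetricUndefinedError("AUC undefined for single-class labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class CVResult:
    """Out-of-fold scores and summary metrics of one cohort evaluation."""

    out_of_fold_scores: np.ndarray
    labels: np.ndarray
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    fold_subsets: List[List[str]] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    seed: Optional[int] = None


def _fold_fit_and_score(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xte: np.ndarray,
    n_sets: int,
    k_max: Optional[int],
) -> Tuple[np.ndarray, np.ndarray]:
    """Rank + forward-select + fit on training rows only; score test rows."""
    ranked = fmrmr_rank(Xtr, ytr, n_sets=n_sets)
    sel = forward_select(ranked, Xtr, ytr, k_max=k_max)
    cols = sel.subset
    model = fit_gaussian_nb(Xtr[:, cols], ytr)
    model.feature_idx = cols
    return predict_posterior(model, Xte[:, cols]), cols


def _table_matrix(table: CohortTable, family: str) -> Tuple[np.ndarray, List[str]]:
    cols = family_columns(family)
    return table.features[cols].to_numpy(dtype=float), cols


def loo_cv(
    table: CohortTable,
    family: str = "all",
    n_sets: int = 3,
    k_max: Optional[int] = None,
) -> CVResult:
    """Leave-one-image-out evaluation with selection nested per fold."""
    X, colnames = _table_matrix(table, family)
    y = table.labels
    n = X.shape[0]
    if n < 3:
        raise CohortError("need at least 3 patients for leave-one-out")
    if np.unique(y).size < 2:
        raise CohortError("both classes required")
    scores = np.empty(n)
    subsets: List[List[str]] = []
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        s, cols = _fold_fit_and_score(X[tr], y[tr], X[~tr], n_sets, k_max)
        scores[i] = s[0]
        subsets.append([colnames[c] for c in cols])
    acc, sn, sp = confusion_metrics(scores, y)
    return CVResult(
        out_of_fold_scores=scores,
        labels=y.copy(),
        auc=roc_auc(scores, y),
        accuracy=acc,
        sensitivity=sn,
        specificity=sp,
        fold_subsets=subsets,
        config={"family": family, "n_sets": n_sets, "cv": "loo"},
    )


def repeated_kfold_cv(
    table: CohortTable,
    k: int = 3,
    repeats: int = 20,
    seed: int = 0,
    family: str = "all",
    n_sets: int = 3,
    k_max: Optional[int] = None,
) -> CVResult:
    """Stratified k-fold CV repeated with fresh seeded partitions.

    Within one repeat every patient is scored exactly once out-of-fold;
    the four metrics are computed from the pooled out-of-fold scores of
    that repeat and then averaged over repeats.  (With k = n a repeat
    reduces to leave-one-image-out.)
    """
    if k < 2 or repeats < 1:
        raise CohortError("need k >= 2 and repeats >= 1")
    X, colnames = _table_matrix(table, family)
    y = table.labels
    per_repeat = np.empty((repeats, 4))
    subsets: List[List[str]] = []
    all_scores = []
    n = len(y)
    for rep in range(repeats):
        if k == n:  # degenerates to leave-one-out; no stratification possible
            splits = [
                (np.concatenate([np.arange(i), np.arange(i + 1, n)]), np.array([i]))
                for i in range(n)
            ]
        else:
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
            splits = skf.split(X, y)
        rep_scores = np.empty(len(y))
        for tr_idx, te_idx in splits:
            s, cols = _fold_fit_and_score(X[tr_idx], y[tr_idx], X[te_idx], n_sets, k_max)
            rep_scores[te_idx] = s
            subsets.append([colnames[c] for c in cols])
        acc, sn, sp = confusion_metrics(rep_scores, y)
        per_repeat[rep] = [roc_auc(rep_scores, y), acc, sn, sp]
        all_scores.append(rep_scores)
    auc, acc, sn, sp = per_repeat.mean(axis=0)
    return CVResult(
        out_of_fold_scores=np.mean(all_scores, axis=0),
        labels=y.copy(),
        auc=float(auc),
        accuracy=float(acc),
        sensitivity=float(sn),
        specificity=float(sp),
        fold_subsets=subsets,
        config={"family": family, "n_sets": n_sets, "cv": f"{k}fold"},
        seed=seed,
    )
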