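import numpy as np
import pandas as pd
import pytest

import tumortex as tx
import tumortex.modeling as mod
from tumortex.errors import CohortError, FitError, MetricUndefinedError
from tumortex.modeling import _loo_scores_nb
from tumortex.pipeline import CohortTable, feature_names

from _oracles import auc_bruteforce


def _random_table(n=12, seed=0, signal=0.0):
    """A CohortTable with random values in all 255 named columns."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, 255))
    X[:, 236] += signal * y  # an ACM2 column
    ids = [f"P{i:03d}" for i in range(n)]
    return CohortTable(
        features=pd.DataFrame(X, index=ids, columns=list(feature_names())),
        labels=y,
        patient_ids=ids,
    )


class TestGaussianNB:
    def test_class_means_and_floored_variances(self):
        X = np.array([[0.0], [0.0], [2.0], [2.0]])
        y = np.array([0, 0, 1, 1])
        m = tx.fit_gaussian_nb(X, y)
        assert m.theta[0, 0] == 0.0 and m.theta[1, 0] == 2.0
        assert (m.var > 0).all()  # zero within-class variance is floored

    def test_single_class_raises(self):
        with pytest.raises(FitError):
            tx.fit_gaussian_nb(np.zeros((4, 2)), np.zeros(4, dtype=int))

    def test_duplicated_dataset_gives_identical_model(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 3))
        y = np.array([0, 1] * 5)
        m1 = tx.fit_gaussian_nb(X, y)
        m2 = tx.fit_gaussian_nb(np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_allclose(m1.theta, m2.theta)
        np.testing.assert_allclose(m1.var, m2.var)

    def test_moments_match_direct_formulas(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 4))
        y = (rng.random(20) < 0.4).astype(int)
        y[:2] = [0, 1]
        m = tx.fit_gaussian_nb(X, y)
        for c in (0, 1):
            np.testing.assert_allclose(m.theta[c], X[y == c].mean(axis=0))
            np.testing.assert_allclose(
                m.var[c], X[y == c].var(axis=0), atol=1e-8
            )

    def test_posterior_at_symmetric_midpoint_is_half(self):
        X = np.array([[-1.0], [1.0], [3.0], [5.0]])
        y = np.array([0, 0, 1, 1])
        m = tx.fit_gaussian_nb(X, y)  # means 0 and 4, equal variances
        assert tx.predict_posterior(m, [[2.0]])[0] == pytest.approx(0.5)

    def test_posterior_closed_form_unit_variances(self):
        # means 0 and 2, unit variances, equal priors, x = 0:
        # P(class0 | x) = e^2 / (1 + e^2), so positive-class posterior is
        # 1 / (1 + e^2)
        m = mod.GaussianNBModel(
            theta=np.array([[0.0], [2.0]]),
            var=np.array([[1.0], [1.0]]),
            priors=np.array([0.5, 0.5]),
        )
        expected = 1.0 / (1.0 + np.exp(2.0))
        assert tx.predict_posterior(m, [[0.0]])[0] == pytest.approx(expected)
        assert tx.predict_posterior(m, [[1.0]])[0] == pytest.approx(0.5)

    def test_posteriors_of_both_classes_sum_to_one(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(16, 3))
        y = np.array([0, 1] * 8)
        m = tx.fit_gaussian_nb(X, y)
        p1 = tx.predict_posterior(m, X)
        m_swapped = mod.GaussianNBModel(
            theta=m.theta[::-1].copy(), var=m.var[::-1].copy(), priors=m.priors
        )
        p0 = tx.predict_posterior(m_swapped, X)
        np.testing.assert_allclose(p1 + p0, 1.0, atol=1e-12)

    def test_loo_downdates_equal_explicit_refits(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(14, 3))
        y = np.array([0, 1] * 7)
        fast = _loo_scores_nb(X, y)
        slow = np.empty(14)
        for i in range(14):
            keep = np.ones(14, dtype=bool)
            keep[i] = False
            m = tx.fit_gaussian_nb(X[keep], y[keep])
            slow[i] = tx.predict_posterior(m, X[i : i + 1])[0]
        np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_agrees_with_sklearn_reference(self):
        from sklearn.naive_bayes import GaussianNB

        rng = np.random.default_rng(21)
        X = rng.normal(size=(30, 5))
        y = (rng.random(30) < 0.5).astype(int)
        y[:2] = [0, 1]
        m = tx.fit_gaussian_nb(X, y)
        ref = GaussianNB(priors=[0.5, 0.5]).fit(X, y)
        ours = tx.predict_posterior(m, X)
        theirs = ref.predict_proba(X)[:, 1]
        np.testing.assert_allclose(ours, theirs, atol=1e-6)


class TestMetrics:
    def test_perfect_separation(self):
        acc, sn, sp = tx.confusion_metrics([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0])
        assert (acc, sn, sp) == (1.0, 1.0, 1.0)

    def test_total_misclassification(self):
        acc, sn, sp = tx.confusion_metrics([0.6, 0.4], [0, 1])
        assert acc == 0.0

    def test_study_cohort_arithmetic(self):
        """10/15 long survivors and 19/20 short survivors correct gives
        Sn = 0.67 and Sp = 0.95 at the study's class sizes."""
        labels = np.array([1] * 15 + [0] * 20)
        scores = np.concatenate(
            [np.full(10, 0.9), np.full(5, 0.1), np.full(19, 0.1), np.full(1, 0.9)]
        )
        acc, sn, sp = tx.confusion_metrics(scores, labels)
        assert sn == pytest.approx(10 / 15)
        assert sp == pytest.approx(19 / 20)
        assert acc == pytest.approx(29 / 35)

    def test_threshold_ties_classify_positive(self):
        acc, sn, sp = tx.confusion_metrics([0.5, 0.5], [1, 0])
        assert sn == 1.0 and sp == 0.0

    def test_single_class_labels_raise(self):
        with pytest.raises(MetricUndefinedError):
            tx.confusion_metrics([0.1, 0.9], [1, 1])
        with pytest.raises(MetricUndefinedError):
            tx.roc_auc([0.1, 0.9], [1, 1])

    def test_auc_perfect_and_all_ties(self):
        assert tx.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert tx.roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_auc_equals_pairwise_rank_statistic(self):
        rng = np.random.default_rng(30)
        for _ in range(5):
            scores = np.round(rng.random(12), 1)  # coarse grid forces ties
            labels = np.array([0, 1] * 6)
            assert tx.roc_auc(scores, labels) == pytest.approx(
                auc_bruteforce(scores, labels), abs=1e-12
            )


class TestCrossValidation:
    def test_loo_produces_one_score_per_patient(self):
        table = _random_table(n=12, seed=1, signal=4.0)
        res = tx.loo_cv(table, family="acm2")
        assert res.out_of_fold_scores.shape == (12,)
        assert len(res.fold_subsets) == 12
        assert 0.0 <= res.auc <= 1.0

    def test_loo_needs_both_classes(self):
        table = _random_table(n=8, seed=2)
        table.labels[:] = 0
        with pytest.raises(CohortError):
            tx.loo_cv(table)

    def test_kfold_equals_loo_when_k_is_n(self):
        table = _random_table(n=6, seed=3, signal=3.0)
        loo = tx.loo_cv(table, family="acm2")
        kf = tx.repeated_kfold_cv(table, k=6, repeats=1, seed=0, family="acm2")
        np.testing.assert_allclose(kf.out_of_fold_scores, loo.out_of_fold_scores)
        assert kf.auc == pytest.approx(loo.auc)

    def test_kfold_runs_k_times_repeats_fits(self):
        table = _random_table(n=12, seed=4, signal=4.0)
        res = tx.repeated_kfold_cv(table, k=3, repeats=2, seed=0, family="acm2")
        assert len(res.fold_subsets) == 6  # k x repeats
        assert 0.0 <= res.auc <= 1.0

    def test_kfold_seeded_determinism(self):
        table = _random_table(n=12, seed=5, signal=4.0)
        r1 = tx.repeated_kfold_cv(table, k=3, repeats=1, seed=7, family="acm2")
        r2 = tx.repeated_kfold_cv(table, k=3, repeats=1, seed=7, family="acm2")
        np.testing.assert_array_equal(r1.out_of_fold_scores, r2.out_of_fold_scores)
        assert r1.auc == r2.auc

    def test_no_leakage_of_test_rows_into_selection_or_fit(self, monkeypatch):
        """Every row handed to rank/select/fit must come from the training
        split; held-out rows are detected by their unique feature values."""
        table = _random_table(n=10, seed=6)
        X_full = table.features.to_numpy()
        seen = []
        original = mod._fold_fit_and_score

        def spy(Xtr, ytr, Xte, n_sets, k_max):
            seen.append((Xtr.copy(), Xte.copy()))
            return original(Xtr, ytr, Xte, n_sets, k_max)

        monkeypatch.setattr(mod, "_fold_fit_and_score", spy)
        tx.loo_cv(table, family="ih")
        assert len(seen) == 10
        for Xtr, Xte in seen:
            tr_set = {round(v, 9) for v in Xtr[:, 0]}
            te_set = {round(v, 9) for v in Xte[:, 0]}
            assert not tr_set & te_set

    def test_label_permutation_calibration(self):
        """Mean LOO AUC over label permutations of a signal-free table sits
        near chance."""
        rng = np.random.default_rng(44)
        aucs = []
        for k in range(12):
            table = _random_table(n=14, seed=100 + k)
            table.labels[:] = rng.permutation(table.labels)
            aucs.append(tx.loo_cv(table, family="ih").auc)
        assert 0.4 <= np.mean(aucs) <= 0.6
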