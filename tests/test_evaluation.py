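"""Confusion metrics, ROC/AUC equivalences and the CV harness."""

import numpy as np
import pytest

from fntstack.evaluation import (
    ConfusionCounts,
    EvaluationError,
    StratificationError,
    confusion,
    cross_validate,
    metrics,
    roc_auc,
    stratified_fold_assignment,
)


def naive_confusion(y_true, y_pred):
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 1 and p == 0:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def pairwise_auc(y_true, scores):
    """Mann-Whitney oracle: P(score_pos > score_neg), ties counted 1/2."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_two_row_case(self):
        c = confusion([1, 0], [1, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_flipping_predictions_swaps_counts(self, rng):
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        c = confusion(y, p)
        cf = confusion(y, 1 - p)
        assert (c.tp, c.tn) == (cf.fn, cf.fp)
        assert (c.fn, c.fp) == (cf.tp, cf.tn)

    def test_matches_naive_counting_oracle(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 200)
            p = rng.integers(0, 2, 200)
            c = confusion(y, p)
            assert (c.tp, c.fp, c.fn, c.tn) == naive_confusion(y, p)

    def test_length_mismatch_raises(self):
        with pytest.raises(EvaluationError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_perfect_counts_give_all_ones(self):
        m = metrics(ConfusionCounts(tp=1, fp=0, fn=0, tn=1))
        assert (m.tpr, m.fpr, m.precision, m.specificity, m.f1) == (
            1.0,
            0.0,
            1.0,
            1.0,
            1.0,
        )

    def test_published_two_fold_row_identities(self):
        # smallest integer confusion matrix consistent with the published
        # 2-fold stacking-ensemble row: 59/8 actives, 4/197 decoys
        m = metrics(ConfusionCounts(tp=59, fn=8, fp=4, tn=197))
        assert m.tpr == pytest.approx(0.880597, abs=5e-7)
        assert m.fpr == pytest.approx(0.019900, abs=5e-7)
        assert m.precision == pytest.approx(0.936508, abs=5e-7)
        assert m.specificity == pytest.approx(0.980100, abs=5e-7)
        assert m.f1 == pytest.approx(0.907692, abs=5e-7)

    def test_specificity_complements_fpr(self, rng):
        for _ in range(50):
            y = rng.integers(0, 2, 100)
            p = rng.integers(0, 2, 100)
            if len(np.unique(y)) < 2:
                continue
            m = metrics(confusion(y, p))
            assert m.specificity == pytest.approx(1 - m.fpr, abs=1e-12)

    def test_zero_denominator_conventions(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, fn=5, tn=5))
        assert m.precision == 1.0  # no positive predictions
        assert m.f1 == 0.0

    def test_single_class_truth_raises(self):
        with pytest.raises(EvaluationError):
            metrics(ConfusionCounts(tp=3, fp=0, fn=2, tn=0))


class TestRocAuc:
    def test_perfect_separation(self):
        roc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert roc.auc == 1.0

    def test_constant_scores_give_half(self):
        roc = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert roc.auc == pytest.approx(0.5)

    def test_trapezoid_equals_rank_statistic(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 80))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.uniform(0, 1, n), 2)  # induce ties
            assert roc_auc(y, scores).auc == pytest.approx(
                pairwise_auc(y, scores), abs=1e-12
            )

    def test_curve_endpoints_and_monotonicity(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        roc = roc_auc(y, rng.uniform(0, 1, 60))
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)

    def test_single_class_raises(self):
        with pytest.raises(EvaluationError):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])


class TestFoldAssignment:
    def test_sizes_balanced_per_class(self):
        y = np.r_[np.ones(88), np.zeros(264)]
        folds = stratified_fold_assignment(np.arange(352), y, 4, seed=0)
        sizes = [int((folds == f).sum()) for f in range(4)]
        assert sizes == [88, 88, 88, 88]
        for f in range(4):
            assert (y[folds == f] == 1).sum() == 22

    def test_keyed_to_row_id_not_order(self, rng):
        y = np.r_[np.ones(20), np.zeros(40)].astype(int)
        ids = np.array([f"r{i:03d}" for i in range(60)])
        folds = stratified_fold_assignment(ids, y, 5, seed=3)
        perm = rng.permutation(60)
        folds_shuffled = stratified_fold_assignment(ids[perm], y[perm], 5, seed=3)
        # map back: fold of a given id must be unchanged
        assert np.array_equal(folds[perm], folds_shuffled)

    def test_small_class_raises(self):
        y = np.r_[np.ones(3), np.zeros(40)]
        with pytest.raises(StratificationError):
            stratified_fold_assignment(np.arange(43), y, 5, seed=0)


class TestCrossValidate:
    @staticmethod
    def oracle_builder(X_train, y_train):
        del X_train, y_train
        # scores equal to the hidden rule used to label the data below
        return lambda X_test: (X_test[:, 0] > 0).astype(float)

    def test_always_correct_model_scores_ones(self, rng):
        X = rng.normal(size=(80, 3))
        y = (X[:, 0] > 0).astype(int)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        cv = cross_validate(X, y, self.oracle_builder, k=4, seed=0)
        m = cv.pooled_metrics
        assert (m.tpr, m.precision, m.specificity, m.f1) == (1, 1, 1, 1)
        assert cv.pooled_roc.auc == 1.0

    def test_fold_confusions_sum_to_pooled(self, rng):
        X = rng.normal(size=(90, 3))
        y = rng.integers(0, 2, 90)
        y[:2] = [0, 1]

        def noisy_builder(X_train, y_train):
            rule = np.sign(np.corrcoef(X_train[:, 0], y_train)[0, 1] or 1)
            return lambda X_test: (rule * X_test[:, 0] > 0).astype(float)

        cv = cross_validate(X, y, noisy_builder, k=3, seed=1)
        total = cv.fold_confusions[0]
        for c in cv.fold_confusions[1:]:
            total = total + c
        p = cv.pooled_confusion
        assert (total.tp, total.fp, total.fn, total.tn) == (
            p.tp,
            p.fp,
            p.fn,
            p.tn,
        )

    def test_reproducible_from_seed(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        cv1 = cross_validate(X, y, self.oracle_builder, k=3, seed=9)
        cv2 = cross_validate(X, y, self.oracle_builder, k=3, seed=9)
        assert np.array_equal(cv1.fold_assignment, cv2.fold_assignment)

    def test_excessive_k_raises(self, rng):
        X = rng.normal(size=(20, 2))
        y = np.r_[np.ones(4), np.zeros(16)].astype(int)
        with pytest.raises(StratificationError):
            cross_validate(X, y, self.oracle_builder, k=6, seed=0)
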