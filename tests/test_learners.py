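"""Trees, boosted selection, metrics, cross-validation, t test."""

import numpy as np
import pytest
from scipy import stats

from adrmine.learners import (
    boosted_selection,
    cross_validate,
    evaluate,
    fit_tree,
    metric_ttest,
    predict_proba,
)
from adrmine.matrix import LabeledDrugSet, NEG, POS, BinaryMatrix


def _matrix(X, drugs=None):
    X = np.asarray(X, dtype=np.uint8)
    drugs = drugs or tuple(f"d{i:02d}" for i in range(X.shape[0]))
    fids = tuple(f"f{j}" for j in range(X.shape[1]))
    return BinaryMatrix(drugs=tuple(drugs), feature_ids=fids, data=X)


def _labels(y, drugs):
    ls = LabeledDrugSet()
    for d, v in zip(drugs, y):
        ls.assignments[d] = POS if v else NEG
    return ls


class TestFitTree:
    def test_perfect_single_feature_gives_depth_one_tree(self):
        X = np.array([[1]] * 6 + [[0]] * 6)
        y = np.array([True] * 6 + [False] * 6)
        model = fit_tree(X, y)
        assert model.clf.get_depth() == 1
        assert (model.predict_proba_pos(X) >= 0.5).tolist() == y.tolist()

    def test_constant_labels_give_single_leaf(self):
        X = np.array([[0], [1], [0], [1], [0], [1]])
        y = np.array([True] * 6)
        model = fit_tree(X, y)
        assert model.clf.get_n_leaves() == 1
        assert predict_proba(model, X).tolist() == [1.0] * 6

    def test_purer_split_preferred(self):
        """(8,2)/(2,8) beats (6,4)/(4,6) by weighted Gini: the root must
        test the first feature."""
        pos_rows = [[1, 1]] * 6 + [[1, 0]] * 2 + [[0, 1]] * 0 + [[0, 0]] * 2
        neg_rows = [[1, 1]] * 2 + [[1, 0]] * 0 + [[0, 1]] * 2 + [[0, 0]] * 6
        X = np.array(pos_rows + neg_rows)
        y = np.array([True] * 10 + [False] * 10)
        assert np.isclose(X[y, 0].sum(), 8) and np.isclose(X[~y, 0].sum(), 2)
        assert np.isclose(X[y, 1].sum(), 6) and np.isclose(X[~y, 1].sum(), 4)
        model = fit_tree(X, y)
        assert model.clf.tree_.feature[0] == 0

    def test_min_leaf_respected(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(40, 5))
        y = rng.random(40) < 0.5
        model = fit_tree(X, y, min_leaf=5)
        counts = model.clf.tree_.n_node_samples[model.clf.tree_.children_left == -1]
        assert (counts >= 5).all()

    def test_leaf_probabilities_are_weight_fractions(self):
        X = np.array([[1]] * 6 + [[0]] * 6)
        y = np.array([True] * 6 + [False] * 6)
        model = fit_tree(X, y)
        assert predict_proba(model, np.array([[1]]))[0] == 1.0
        assert predict_proba(model, np.array([[0]]))[0] == 0.0


class TestBoostedSelection:
    def test_perfect_separator_selected_alone_with_early_stop(self):
        rng = np.random.default_rng(1)
        noise = rng.integers(0, 2, size=(20, 3))
        sep = np.array([[1]] * 10 + [[0]] * 10)
        X = np.hstack([noise[:, :1], sep, noise[:, 1:]])
        y = np.array([True] * 10 + [False] * 10)
        assert boosted_selection(X, y) == {1}

    def test_constant_features_select_nothing(self):
        X = np.ones((12, 4), dtype=int)
        y = np.array([True] * 6 + [False] * 6)
        assert boosted_selection(X, y) == set()

    def test_selection_subset_of_variable_features(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, size=(30, 8))
        X[:, 3] = 1  # constant
        y = rng.random(30) < 0.5
        selected = boosted_selection(X, y)
        assert 3 not in selected
        assert selected <= set(range(8))


class TestEvaluate:
    def test_perfect_scores_give_unit_metrics(self):
        m = evaluate([1.0, 1.0, 0.0, 0.0], [True, True, False, False])
        assert (m.precision, m.recall, m.f1, m.accuracy, m.auc) == (1, 1, 1, 1, 1)

    def test_confusion_count_formulas(self):
        # TP=3, FP=1, FN=2, TN=4
        scores = [1, 1, 1, 0, 0] + [1, 0, 0, 0, 0]
        labels = [True] * 5 + [False] * 5
        m = evaluate(scores, labels)
        assert m.precision == 0.75
        assert m.recall == 0.6
        assert m.accuracy == 0.7
        assert np.isclose(m.f1, 2 * 0.75 * 0.6 / (0.75 + 0.6))

    def test_constant_scores_auc_half_and_precision_zero_convention(self):
        m = evaluate([0.2] * 6, [True, False, True, False, True, False])
        assert m.auc == 0.5
        assert m.precision == 0.0  # no positive predictions

    def test_single_class_auc_missing(self):
        m = evaluate([0.1, 0.9], [True, True])
        assert m.auc is None

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_normalized_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=20)
        labels = rng.random(20) < 0.5
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        u = stats.mannwhitneyu(scores[labels], scores[~labels]).statistic
        expected = u / (labels.sum() * (~labels).sum())
        assert np.isclose(evaluate(scores, labels).auc, expected)


class TestCrossValidate:
    def _data(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        signal = np.array([[1]] * (n // 2) + [[0]] * (n // 2))
        noise = rng.integers(0, 2, size=(n, 5))
        X = np.hstack([signal, noise])
        y = np.array([True] * (n // 2) + [False] * (n // 2))
        flip = rng.random(n) < 0.1
        X[flip, 0] = 1 - X[flip, 0]
        bm = _matrix(X)
        return bm, _labels(y, bm.drugs)

    def test_folds_partition_drugs_with_balanced_sizes(self):
        bm, labeled = self._data()
        report = cross_validate(bm, labeled, n_folds=10, seed=3)
        assert sorted(report.fold_assignment) == sorted(bm.drugs)
        sizes = np.bincount(list(report.fold_assignment.values()))
        assert sizes.max() - sizes.min() <= 1

    def test_identical_seed_identical_report(self):
        bm, labeled = self._data()
        a = cross_validate(bm, labeled, seed=5)
        b = cross_validate(bm, labeled, seed=5)
        assert [m.as_dict() for m in a.folds] == [m.as_dict() for m in b.folds]
        assert a.fold_assignment == b.fold_assignment

    def test_strong_signal_recovered(self):
        bm, labeled = self._data()
        report = cross_validate(bm, labeled, seed=1)
        assert report.mean.auc > 0.8


class TestMetricTTest:
    def test_identical_samples(self):
        t, p = metric_ttest([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert (t, p) == (0.0, 1.0)

    def test_antisymmetric_in_arguments(self):
        a, b = [0.1, 0.3, 0.2], [0.6, 0.4, 0.5]
        t1, p1 = metric_ttest(a, b)
        t2, p2 = metric_ttest(b, a)
        assert np.isclose(t1, -t2) and np.isclose(p1, p2)

    def test_welch_statistic_closed_form(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [2.0, 4.0, 6.0, 8.0, 10.0]
        t, p = metric_ttest(a, b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        expected = (np.mean(a) - np.mean(b)) / np.sqrt(va / 5 + vb / 5)
        assert np.isclose(t, expected)
        assert 0 < p < 1
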