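"""Boosted wrapper feature selection, class-balanced trees, CV, metrics.

The learning pipeline mirrors a standard wrapper-based selection scheme:
up to 10 boosted CART trees (Gini impurity, all features at each split,
at least 5 examples per leaf, class-balanced instance weights) are fit
on the training part, the union of features used by any tree is kept,
and a final tree on the selected features is evaluated on the held-out
part.  Performance is reported as precision, recall and F1 (reference
class POS), accuracy, and AUC-ROC, averaged over a 10-fold
cross-validation whose split is drawn once at random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeClassifier

from .matrix import BinaryMatrix, LabeledDrugSet, POS, to_binary_matrix
from .mining import FeatureTable

DEFAULT_MIN_LEAF = 5
DEFAULT_BOOST_ROUNDS = 10
DEFAULT_N_FOLDS = 10


def balanced_weights(y: np.ndarray) -> np.ndarray:
    """Instance weights normalizing each class's total weight to 1/2."""
    y = np.asarray(y, dtype=bool)
    w = np.empty(len(y), dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos:
        w[y] = 0.5 / n_pos
    if n_neg:
        w[~y] = 0.5 / n_neg
    return w


@dataclass
class TreeModel:
    """A fitted class-balanced CART tree over binary features."""

    clf: DecisionTreeClassifier
    n_features: int

    def features_used(self) -> set[int]:
        feats = self.clf.tree_.feature
        return set(int(f) for f in feats if f >= 0)

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        """POS weight fraction of the leaf each instance is routed to."""
        proba = self.clf.predict_proba(np.asarray(X))
        classes = list(self.clf.classes_)
        if True not in classes:
            return np.zeros(len(proba))
        return proba[:, classes.index(True)]


def fit_tree(
    X: np.ndarray,
    y: np.ndarray,
    min_leaf: int = DEFAULT_MIN_LEAF,
    seed: int = 0,
) -> TreeModel:
    """Greedy Gini-minimizing tree on feature presence, class-balanced.

    All features are candidates at every split; every leaf keeps at
    least ``min_leaf`` training examples.  A single-class input yields a
    single-leaf model.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=bool)
    clf = DecisionTreeClassifier(
        criterion="gini",
        min_samples_leaf=min_leaf,
        max_features=None,
        min_impurity_decrease=1e-9,  # suppress zero-gain splits on float-level impurity
        random_state=seed,
    )
    clf.fit(X, y, sample_weight=balanced_weights(y))
    return TreeModel(clf=clf, n_features=X.shape[1])


def predict_proba(model: TreeModel, X: np.ndarray) -> np.ndarray:
    return model.predict_proba_pos(X)


def boosted_selection(
    X: np.ndarray,
    y: np.ndarray,
    max_rounds: int = DEFAULT_BOOST_ROUNDS,
    min_leaf: int = DEFAULT_MIN_LEAF,
    seed: int = 0,
) -> set[int]:
    """Wrapper feature selection with discrete boosting.

    Up to ``max_rounds`` CART trees (same parameters as the final tree)
    are boosted from class-balanced initial weights; boosting stops
    early on a perfect fit.  Returns the indices of features used in at
    least one tree — necessarily a subset of the non-constant features.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=bool)
    if X.shape[1] == 0:
        return set()
    variable = np.nonzero(X.min(axis=0) != X.max(axis=0))[0]
    if len(variable) == 0 or len(np.unique(y)) < 2:
        return set()
    Xv = X[:, variable]
    base = DecisionTreeClassifier(
        criterion="gini",
        min_samples_leaf=min_leaf,
        max_features=None,
        min_impurity_decrease=1e-9,
        random_state=seed,
    )
    booster = AdaBoostClassifier(estimator=base, n_estimators=max_rounds, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        booster.fit(Xv, y, sample_weight=balanced_weights(y))
    selected: set[int] = set()
    for est in booster.estimators_:
        feats = est.tree_.feature
        selected.update(int(variable[f]) for f in feats if f >= 0)
    return selected


@dataclass
class Metrics:
    precision: float
    recall: float
    f1: float
    accuracy: float
    auc: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "auc": self.auc,
        }


def evaluate(scores: Sequence[float], labels: Sequence[bool], threshold: float = 0.5) -> Metrics:
    """Thresholded confusion metrics plus rank-based AUC.

    Precision is defined as 0 when no positive prediction is made; AUC
    uses midranks for ties (so constant scores give 0.5) and is reported
    as missing when the labels are single-class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pred = scores >= threshold
    precision = precision_score(labels, pred, zero_division=0)
    recall = recall_score(labels, pred, zero_division=0)
    f1 = f1_score(labels, pred, zero_division=0)
    accuracy = accuracy_score(labels, pred)
    if labels.all() or not labels.any():
        auc = None
    else:
        auc = float(roc_auc_score(labels, scores))
    return Metrics(float(precision), float(recall), float(f1), float(accuracy), auc)


def _mean_metrics(folds: list[Metrics]) -> Metrics:
    aucs = [m.auc for m in folds if m.auc is not None]
    return Metrics(
        precision=float(np.mean([m.precision for m in folds])),
        recall=float(np.mean([m.recall for m in folds])),
        f1=float(np.mean([m.f1 for m in folds])),
        accuracy=float(np.mean([m.accuracy for m in folds])),
        auc=float(np.mean(aucs)) if aucs else None,
    )


@dataclass
class CVReport:
    folds: list[Metrics]
    mean: Metrics
    fold_assignment: dict[str, int]
    seed: int
    selected_per_fold: list[set[str]] = field(default_factory=list)

    def write_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("fold\tprecision\trecall\tf1\taccuracy\tauc\n")
            for i, m in enumerate(self.folds):
                auc = "" if m.auc is None else f"{m.auc:.6f}"
                handle.write(
                    f"{i}\t{m.precision:.6f}\t{m.recall:.6f}\t{m.f1:.6f}\t{m.accuracy:.6f}\t{auc}\n"
                )
            m = self.mean
            auc = "" if m.auc is None else f"{m.auc:.6f}"
            handle.write(
                f"mean\t{m.precision:.6f}\t{m.recall:.6f}\t{m.f1:.6f}\t{m.accuracy:.6f}\t{auc}\n"
            )


def _as_matrix(table: FeatureTable | BinaryMatrix, labeled: LabeledDrugSet) -> BinaryMatrix:
    if isinstance(table, BinaryMatrix):
        return table
    return to_binary_matrix(table, labeled)


def cross_validate(
    table: FeatureTable | BinaryMatrix,
    labeled: LabeledDrugSet,
    n_folds: int = DEFAULT_N_FOLDS,
    seed: int = 0,
    min_leaf: int = DEFAULT_MIN_LEAF,
    boost_rounds: int = DEFAULT_BOOST_ROUNDS,
    model_factory: Callable | None = None,
) -> CVReport:
    """Cross-validate selection + learning with a single random split.

    Per fold, boosted selection runs on the training part only, the
    final model is fit on the selected features, and metrics are
    computed on the held-out part.  ``model_factory(X, y, seed)`` may
    replace the default class-balanced tree; it must return an object
    with a ``predict_proba_pos(X)`` method.  Folds whose training part
    is single-class are skipped with a warning.
    """
    bm = _as_matrix(table, labeled)
    y = bm.labels_vector(labeled)
    if len(bm.drugs) < n_folds:
        raise ValueError(f"need at least {n_folds} labeled drugs, got {len(bm.drugs)}")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_assignment: dict[str, int] = {}
    folds: list[Metrics] = []
    selected_per_fold: list[set[str]] = []
    for fold_idx, (train, test) in enumerate(kf.split(bm.data)):
        for i in test:
            fold_assignment[bm.drugs[i]] = fold_idx
        y_train = y[train]
        if y_train.all() or not y_train.any():
            warnings.warn(f"fold {fold_idx}: a class is absent from training; fold skipped")
            continue
        selected = sorted(
            boosted_selection(
                bm.data[train], y_train, max_rounds=boost_rounds, min_leaf=min_leaf, seed=seed
            )
        )
        selected_per_fold.append({bm.feature_ids[j] for j in selected})
        if not selected:
            scores = np.full(len(test), 0.5)
        else:
            X_train = bm.data[train][:, selected]
            X_test = bm.data[test][:, selected]
            if model_factory is None:
                model = fit_tree(X_train, y_train, min_leaf=min_leaf, seed=seed)
            else:
                model = model_factory(X_train, y_train, seed)
            scores = model.predict_proba_pos(X_test)
        folds.append(evaluate(scores, y[test]))
    return CVReport(
        folds=folds,
        mean=_mean_metrics(folds),
        fold_assignment=fold_assignment,
        seed=seed,
        selected_per_fold=selected_per_fold,
    )


def metric_ttest(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) two-sample t test.

    Degenerate zero-variance samples with equal means give (0, 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return math_inf_signed(np.mean(a) - np.mean(b)), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def math_inf_signed(delta: float) -> float:
    return float("inf") if delta > 0 else float("-inf")
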