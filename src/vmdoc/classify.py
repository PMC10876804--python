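"""Cross-validated classifier evaluation and the accuracy-comparison arithmetic.

Four conventional classifiers (KNN, linear SVM, decision tree, ensemble of
bagged trees) are evaluated with stratified 10-fold cross-validation:
features are z-scored with statistics fit on the training rows of each fold,
predictions are pooled over folds into one confusion matrix, and accuracy /
macro precision / macro recall / F1 are reported in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable

__all__ = [
    "ClassifierSpec",
    "EvalReport",
    "CLASSIFIER_KINDS",
    "run_cv",
    "metrics",
    "relative_improvement",
    "absolute_improvement",
]

CLASSIFIER_KINDS = ("knn", "linear_svm", "decision_tree", "ensemble_bagged_tree")


@dataclass
class ClassifierSpec:
    """Which classifier to run and its (fixed, not searched) hyperparameters."""

    kind: str = "ensemble_bagged_tree"
    knn_k: int = 5
    svm_c: float = 1.0
    tree_criterion: str = "gini"
    ebt_n_trees: int = 30
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.ebt_n_trees < 2:
            raise ValueError("ebt_n_trees must be >= 2")

    def build(self):
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=self.knn_k)
        if self.kind == "linear_svm":
            return SVC(kernel="linear", C=self.svm_c)
        if self.kind == "decision_tree":
            return DecisionTreeClassifier(criterion=self.tree_criterion,
                                          random_state=self.random_seed)
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(criterion=self.tree_criterion),
            n_estimators=self.ebt_n_trees,
            random_state=self.random_seed,
        )


@dataclass
class EvalReport:
    """Pooled-fold evaluation of one classifier on one feature table."""

    classifier: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    class_order: List[str]
    fold_assignment: Dict[str, int]
    seed: int
    n_folds: int
    n_features_used: int

    def as_dict(self) -> Dict:
        return {
            "classifier": self.classifier,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion": self.confusion.tolist(),
            "class_order": self.class_order,
            "seed": self.seed,
            "n_folds": self.n_folds,
            "n_features_used": self.n_features_used,
        }


def metrics(confusion: np.ndarray) -> Tuple[float, float, float, float]:
    """(accuracy, macro precision, macro recall, F1) in percent.

    Rows are true classes, columns predictions.  Per-class precision or
    recall with an empty denominator contributes 0 to the macro average
    (with a warning); F1 is the harmonic mean of the macro precision and
    macro recall.
    """
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(c < 0):
        raise ValueError("confusion matrix must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(c)
    col_sums = c.sum(axis=0)
    row_sums = c.sum(axis=1)
    prec = np.zeros(c.shape[0])
    rec = np.zeros(c.shape[0])
    for k in range(c.shape[0]):
        if col_sums[k] > 0:
            prec[k] = diag[k] / col_sums[k]
        else:
            warnings.warn(f"class {k}: no predictions; precision counted as 0",
                          RuntimeWarning, stacklevel=2)
        if row_sums[k] > 0:
            rec[k] = diag[k] / row_sums[k]
        else:
            warnings.warn(f"class {k}: no true instances; recall counted as 0",
                          RuntimeWarning, stacklevel=2)
    accuracy = 100.0 * diag.sum() / total
    precision = 100.0 * prec.mean()
    recall = 100.0 * rec.mean()
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return accuracy, precision, recall, f1


def run_cv(table: FeatureTable, spec: Optional[ClassifierSpec] = None,
           k_folds: int = 10, seed: int = 0,
           feature_selector: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None,
           ) -> EvalReport:
    """Stratified k-fold cross-validation of one classifier.

    Per fold: optional in-fold feature selection (``feature_selector(train_X,
    train_y) -> column mask``), z-scoring fit on training rows only, fit,
    predict; predictions are pooled over folds into one confusion matrix.
    If the smallest class has fewer than ``k_folds`` members the fold count
    is reduced with a warning.  Deterministic given the seed.
    """
    if spec is None:
        spec = ClassifierSpec()
    x = np.asarray(table.values, dtype=float)
    y = np.asarray(table.labels)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature table contains non-finite values")
    classes = sorted(set(table.labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    min_count = min(int((y == c).sum()) for c in classes)
    folds = k_folds
    if min_count < k_folds:
        folds = max(2, min_count)
        warnings.warn(f"smallest class has {min_count} subjects; "
                      f"reducing folds {k_folds} -> {folds}", RuntimeWarning,
                      stacklevel=2)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    fold_assignment: Dict[str, int] = {}
    n_feat_used = x.shape[1]
    for fold_i, (tr, te) in enumerate(skf.split(x, y)):
        x_tr, x_te = x[tr], x[te]
        if feature_selector is not None:
            mask = np.asarray(feature_selector(x_tr, y[tr]), dtype=bool)
            if mask.sum() == 0:  # selector kept nothing; fall back to all
                mask = np.ones(x.shape[1], dtype=bool)
            x_tr, x_te = x_tr[:, mask], x_te[:, mask]
            n_feat_used = int(mask.sum())
        scaler = StandardScaler().fit(x_tr)
        clf = spec.build()
        clf.fit(scaler.transform(x_tr), y[tr])
        y_pred[te] = clf.predict(scaler.transform(x_te))
        for i in te:
            fold_assignment[table.subject_ids[i]] = fold_i

    idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for yt, yp in zip(y, y_pred):
        confusion[idx[yt], idx[yp]] += 1
    acc, prec, rec, f1 = metrics(confusion)
    return EvalReport(classifier=spec.kind, accuracy=acc, precision=prec,
                      recall=rec, f1=f1, confusion=confusion,
                      class_order=classes, fold_assignment=fold_assignment,
                      seed=seed, n_folds=folds, n_features_used=n_feat_used)


def relative_improvement(new_acc: float, ref_acc: float) -> float:
    """Percent change (new - ref) / ref * 100; report tables round to 1 decimal."""
    if ref_acc <= 0:
        raise ValueError("reference accuracy must be > 0")
    return (new_acc - ref_acc) / ref_acc * 100.0


def absolute_improvement(sel_acc: float, all_acc: float) -> float:
    """Difference in percentage points (may be negative)."""
    return sel_acc - all_acc
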