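"""Classifier harness, subject-disjoint k-fold CV, and binary/macro metrics.

Folds are built over subjects, never over samples: a person's trials are all
in training or all in testing, because a deployed detector must work for
people it has never seen.  Binary metrics follow the standard confusion-
matrix definitions (sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
accuracy, F1); multi-class metrics are macro scores — the unweighted mean of
the per-class one-vs-rest metric, giving each class equal importance
regardless of its prevalence.  AUROC is the rank statistic (probability that
a positive sample outscores a negative one, ties counting one half), macro-
averaged one-vs-rest in the multi-class case.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import feature_names, minmax_apply, minmax_fit

logger = logging.getLogger(__name__)

ALGORITHMS = ("KNN", "SVM", "DT", "RF", "GB")


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("zero denominator in %s; returning 0", what)
        return 0.0
    return num / den


@dataclass(frozen=True)
class FoldSplit:
    """Subject-level assignment of every subject to exactly one of k folds."""

    k: int
    assignments: dict[str, int]

    def __post_init__(self) -> None:
        folds = set(self.assignments.values())
        if not folds <= set(range(self.k)):
            raise ValueError("fold indices must lie in [0, k)")
        sizes = [list(self.assignments.values()).count(i) for i in range(self.k)]
        if max(sizes) - min(sizes) > 1:
            raise ValueError(f"fold sizes {sizes} differ by more than one subject")

    def test_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignments.items() if f == fold)

    def train_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignments.items() if f != fold)


def make_subject_folds(subjects: Sequence[str], k: int = 5, seed: int = 0) -> FoldSplit:
    """Shuffle the unique subjects with the given seed, then deal them
    round-robin into k folds (sizes differ by at most one)."""
    unique = sorted(set(subjects))
    if k > len(unique):
        raise ValueError(f"k={k} exceeds number of subjects ({len(unique)})")
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    return FoldSplit(k=k, assignments={s: i % k for i, s in enumerate(order)})


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows are true classes, columns predicted."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be square over the class list")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes: Sequence[str]) -> "ConfusionMatrix":
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred, strict=True):
            counts[idx[t], idx[p]] += 1
        return cls(classes=tuple(classes), counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, i: int) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) treating class i as positive."""
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = int(self.total - tp - fn - fp)
        return tp, fp, fn, tn


@dataclass
class MetricSet:
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    auroc: float | None = None

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auroc": self.auroc,
        }


def binary_metrics(cm: ConfusionMatrix, positive: str | None = None) -> MetricSet:
    """Sensitivity, specificity, accuracy and F1 of a 2x2 confusion matrix.

    The positive class defaults to the second class in the matrix ordering.
    """
    if len(cm.classes) != 2:
        raise ValueError("binary_metrics requires a 2-class matrix")
    pos = cm.classes.index(positive) if positive is not None else 1
    tp, fp, fn, tn = cm.one_vs_rest(pos)
    return MetricSet(
        sensitivity=_safe_div(tp, tp + fn, "sensitivity"),
        specificity=_safe_div(tn, tn + fp, "specificity"),
        accuracy=_safe_div(tp + tn, cm.total, "accuracy"),
        f1=_safe_div(2 * tp, 2 * tp + fp + fn, "f1"),
    )


def macro_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Macro (unweighted per-class one-vs-rest average) SE, SP and F1.

    Accuracy is the usual multi-class accuracy, trace / total.
    """
    if len(cm.classes) < 2:
        raise ValueError("macro_metrics requires at least 2 classes")
    se, sp, f1 = [], [], []
    for i in range(len(cm.classes)):
        tp, fp, fn, tn = cm.one_vs_rest(i)
        se.append(_safe_div(tp, tp + fn, f"macro SE[{cm.classes[i]}]"))
        sp.append(_safe_div(tn, tn + fp, f"macro SP[{cm.classes[i]}]"))
        f1.append(_safe_div(2 * tp, 2 * tp + fp + fn, f"macro F1[{cm.classes[i]}]"))
    return MetricSet(
        sensitivity=float(np.mean(se)),
        specificity=float(np.mean(sp)),
        accuracy=_safe_div(np.trace(cm.counts), cm.total, "accuracy"),
        f1=float(np.mean(f1)),
    )


def _binary_auroc(scores: np.ndarray, is_pos: np.ndarray) -> float:
    """Mann-Whitney rank AUROC; ties count one half."""
    n_pos = int(is_pos.sum())
    n_neg = int((~is_pos).sum())
    ranks = rankdata(scores)
    u = ranks[is_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def auroc(scores: np.ndarray, labels: Sequence[str], classes: Sequence[str]) -> float:
    """AUROC from per-class scores.

    Binary: the rank statistic with the second listed class as positive,
    using its score column (or a 1-D score).  Multi-class: the unweighted
    mean of the one-vs-rest binary AUROCs (macro averaging).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    present = set(labels)
    if len(present) < 2:
        raise ValueError("AUROC requires at least one sample of each class")
    if len(classes) == 2:
        col = scores if scores.ndim == 1 else scores[:, 1]
        return _binary_auroc(col, labels == classes[1])
    if scores.ndim != 2 or scores.shape[1] != len(classes):
        raise ValueError("multi-class AUROC needs an (n, n_classes) score matrix")
    aucs = []
    for i, cls in enumerate(classes):
        if cls not in present:
            logger.warning("class %s absent; skipped in macro AUROC", cls)
            continue
        aucs.append(_binary_auroc(scores[:, i], labels == cls))
    return float(np.mean(aucs))


def make_classifier(name: str, seed: int | None = None, params: dict | None = None):
    """Instantiate one of the five classifiers at its pinned defaults.

    The defaults are written out explicitly so results do not drift with
    library versions: KNN (k=5, Euclidean, uniform votes); SVM (RBF, C=1,
    gamma scaled by feature variance, one-vs-one multi-class); DT (Gini,
    best splits, unbounded depth); RF (100 trees, Gini, sqrt features per
    split); GB (100 stages, learning rate 0.1, log-loss, depth 3).
    """
    params = params or {}
    if name == "KNN":
        base = dict(n_neighbors=5, weights="uniform", metric="minkowski", p=2)
        return KNeighborsClassifier(**{**base, **params})
    if name == "SVM":
        base = dict(C=1.0, kernel="rbf", gamma="scale", decision_function_shape="ovr")
        return SVC(**{**base, **params})
    if name == "DT":
        base = dict(criterion="gini", splitter="best", max_depth=None, random_state=seed)
        return DecisionTreeClassifier(**{**base, **params})
    if name == "RF":
        base = dict(
            n_estimators=100, criterion="gini", max_features="sqrt", random_state=seed
        )
        return RandomForestClassifier(**{**base, **params})
    if name == "GB":
        base = dict(
            n_estimators=100, learning_rate=0.1, loss="log_loss", max_depth=3,
            random_state=seed,
        )
        return GradientBoostingClassifier(**{**base, **params})
    raise ValueError(f"unknown algorithm {name!r}; choose from {ALGORITHMS}")


def train_classifier(name, X_train, y_train, seed: int | None = None, params=None):
    """Fit one of the five classifiers on a normalized training matrix."""
    model = make_classifier(name, seed=seed, params=params)
    return model.fit(X_train, y_train)


def predict_with_scores(model, X, classes: Sequence[str]):
    """Predicted labels plus per-class scores aligned to ``classes``.

    Uses ``predict_proba`` where available, otherwise ``decision_function``
    (the SVM case).  Returns ``(labels, scores)`` with scores of shape
    (n, n_classes), or (n,) for a binary decision function.
    """
    labels = model.predict(X)
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        order = {c: i for i, c in enumerate(model.classes_)}
        scores = np.column_stack(
            [
                proba[:, order[c]] if c in order else np.zeros(len(X))
                for c in classes
            ]
        )
        return labels, scores
    scores = model.decision_function(X)
    if scores.ndim == 1:
        return labels, scores
    order = {c: i for i, c in enumerate(model.classes_)}
    scores = np.column_stack(
        [scores[:, order[c]] if c in order else np.zeros(len(X)) for c in classes]
    )
    return labels, scores


@dataclass
class FoldResult:
    fold: int
    test_subjects: list[str]
    cm: ConfusionMatrix
    metrics: MetricSet


@dataclass
class EvaluationReport:
    """Per-fold confusion matrices and metrics plus mean/sd aggregates."""

    algorithm: str
    classes: tuple[str, ...]
    folds: list[FoldResult]
    config: dict = field(default_factory=dict)

    def summary(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for key in ("sensitivity", "specificity", "accuracy", "f1", "auroc"):
            vals = [
                getattr(f.metrics, key)
                for f in self.folds
                if getattr(f.metrics, key) is not None
            ]
            if vals:
                out[key] = {
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals)),
                    "per_fold": [float(v) for v in vals],
                }
        return out

    def mean(self, key: str) -> float:
        return self.summary()[key]["mean"]

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "classes": list(self.classes),
            "config": self.config,
            "folds": [
                {
                    "fold": f.fold,
                    "test_subjects": f.test_subjects,
                    "confusion_matrix": f.cm.counts.tolist(),
                    "metrics": f.metrics.as_dict(),
                }
                for f in self.folds
            ],
            "summary": self.summary(),
        }

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path


def cross_validate(
    features: pd.DataFrame,
    algorithm: str,
    folds: FoldSplit,
    label_col: str = "label",
    seed: int | None = 0,
    normalize_scope: str = "train",
    classes: Sequence[str] | None = None,
    params: dict | None = None,
) -> EvaluationReport:
    """Subject-disjoint k-fold cross-validation of one algorithm.

    ``features`` is a frame from the feature-extraction stage: the 88
    canonical feature columns plus at least ``subject`` and ``label_col``.
    Per fold, the min-max scaler is fitted on the training rows only
    (``normalize_scope="train"``; ``"global"`` fits once on everything),
    the model is trained and evaluated on the held-out subjects, and a
    confusion matrix plus metric set is recorded.  Folds whose test split
    contains a single class get no AUROC (warned, omitted from aggregates).
    """
    if normalize_scope not in ("train", "global"):
        raise ValueError("normalize_scope must be 'train' or 'global'")
    cols = feature_names()
    X = features[cols].to_numpy()
    y = features[label_col].astype(str).to_numpy()
    subj = features["subject"].astype(str).to_numpy()
    if classes is None:
        classes = tuple(sorted(set(y)))
    else:
        classes = tuple(classes)

    missing = set(subj) - set(folds.assignments)
    if missing:
        raise ValueError(f"subjects missing from fold split: {sorted(missing)[:5]}")

    global_scaler = minmax_fit(X) if normalize_scope == "global" else None
    results: list[FoldResult] = []
    for fold in range(folds.k):
        test_subjects = folds.test_subjects(fold)
        test_mask = np.isin(subj, test_subjects)
        train_mask = ~test_mask
        assert not (set(subj[train_mask]) & set(subj[test_mask]))
        scaler = global_scaler or minmax_fit(X[train_mask])
        X_train = minmax_apply(scaler, X[train_mask])
        X_test = minmax_apply(scaler, X[test_mask])
        model = train_classifier(algorithm, X_train, y[train_mask], seed=seed, params=params)
        y_pred, scores = predict_with_scores(model, X_test, classes)
        cm = ConfusionMatrix.from_predictions(y[test_mask], y_pred, classes)
        metrics = binary_metrics(cm) if len(classes) == 2 else macro_metrics(cm)
        if len(set(y[test_mask])) < 2:
            logger.warning("fold %d test split has a single class; AUROC omitted", fold)
        else:
            metrics.auroc = auroc(scores, y[test_mask], classes)
        results.append(
            FoldResult(fold=fold, test_subjects=test_subjects, cm=cm, metrics=metrics)
        )
    return EvaluationReport(
        algorithm=algorithm,
        classes=classes,
        folds=results,
        config={
            "k": folds.k,
            "seed": seed,
            "normalize_scope": normalize_scope,
            "label_col": label_col,
        },
    )
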