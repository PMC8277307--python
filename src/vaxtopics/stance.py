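"""One-vs-all L1-regularized logistic stance classification.

Three binary L1-penalized logistic models (anti / pro / neutral, each
against the rest) are fitted on training data balanced by random minority
oversampling; prediction assigns each text to the class whose binary model
gives the highest sigmoid confidence, with ties broken by the fixed class
order anti < pro < neutral.  Evaluation uses stratified k-fold
cross-validation with one pooled confusion matrix, plus the usual
per-class precision / recall / F-measure and a binary collapse that
merges the pro and anti classes to measure stance-vs-neutral screening.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .features import TweetVectorizer, Vocabulary

__all__ = [
    "CLASS_ORDER",
    "StanceClassifier",
    "oversample",
    "compute_metrics",
    "collapse_binary",
    "EvaluationReport",
    "cross_validate",
    "save_model",
    "load_model",
]

#: Fixed class order used for confusion matrices and tie-breaking.
CLASS_ORDER = ("anti", "pro", "neutral")


def oversample(
    labels: Sequence, seed: int | None = None, classes: Sequence | None = None
) -> np.ndarray:
    """Row-index multiset balancing all classes up to the majority count.

    All original indices are retained (in order); extra indices are drawn
    with replacement from each minority class until every class matches
    the majority-class count.  Deterministic per seed.
    """
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    counts = {c: int(np.sum(labels == c)) for c in classes}
    for c, n in counts.items():
        if n == 0:
            raise ValueError(f"class {c!r} has zero examples; cannot oversample")
    majority = max(counts.values())
    rng = np.random.default_rng(seed)
    extra = []
    for c in classes:
        deficit = majority - counts[c]
        if deficit:
            pool = np.flatnonzero(labels == c)
            extra.append(rng.choice(pool, size=deficit, replace=True))
    parts = [np.arange(len(labels))] + extra
    return np.concatenate(parts)


class StanceClassifier(ClassifierMixin, BaseEstimator):
    """One-vs-all L1-logistic classifier with minority oversampling.

    Parameters
    ----------
    C : float
        Inverse regularization strength of each binary model (the default
        C=1 is used without tuning; the penalty weight convention is
        lambda = 1/C).
    oversample : bool
        Balance the training set by random oversampling before fitting.
    class_order : tuple
        Canonical class order; classes present in ``y`` keep this order
        (others, if any, are appended sorted).  Also the tie-break order.
    random_state : int or None
        Seed for oversampling and the solvers.

    Attributes
    ----------
    classes_ : ndarray
        Classes in canonical order.
    coef_ : ndarray of shape (n_classes, n_features)
        Per-class binary-model weight vectors.
    intercept_ : ndarray of shape (n_classes,)
    """

    def __init__(
        self,
        C: float = 1.0,
        oversample: bool = True,
        class_order: tuple = CLASS_ORDER,
        random_state: int | None = None,
    ) -> None:
        self.C = C
        self.oversample = oversample
        self.class_order = class_order
        self.random_state = random_state

    def fit(self, X, y) -> "StanceClassifier":
        if self.C <= 0:
            raise ValueError("C must be positive")
        y = np.asarray(y)
        present = set(np.unique(y).tolist())
        if len(present) < 2:
            raise ValueError("need at least two classes to train one-vs-all models")
        ordered = [c for c in self.class_order if c in present]
        ordered += sorted(present - set(self.class_order), key=str)
        self.classes_ = np.asarray(ordered)

        if self.oversample:
            idx = oversample(y, seed=self.random_state)
            X_fit = X[idx]
            y_fit = y[idx]
        else:
            X_fit, y_fit = X, y

        self.models_ = []
        for c in self.classes_:
            binary = (y_fit == c).astype(int)
            # l1_ratio=1.0 selects the pure l1 penalty
            m = LogisticRegression(
                l1_ratio=1.0,
                C=self.C,
                solver="liblinear",
                max_iter=1000,
                random_state=self.random_state,
            )
            m.fit(X_fit, binary)
            self.models_.append(m)
        self.coef_ = np.vstack([m.coef_[0] for m in self.models_])
        self.intercept_ = np.array([float(m.intercept_[0]) for m in self.models_])
        self.n_features_in_ = X.shape[1]
        return self

    def _check_width(self, X) -> None:
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature width {X.shape[1]} != trained width {self.n_features_in_}"
            )

    def decision_function(self, X) -> np.ndarray:
        """Per-class linear scores w.x + w0, shape (n, n_classes)."""
        check_is_fitted(self, "coef_")
        self._check_width(X)
        return np.asarray(X @ self.coef_.T) + self.intercept_

    def predict_confidence(self, X) -> np.ndarray:
        """Per-class binary sigmoid confidences sigma(w.x + w0)."""
        return expit(self.decision_function(X))

    def predict_proba(self, X) -> np.ndarray:
        """Sigmoid confidences normalized to sum to one per row."""
        conf = self.predict_confidence(X)
        total = conf.sum(axis=1, keepdims=True)
        n = conf.shape[1]
        with np.errstate(invalid="ignore"):
            proba = np.where(total > 0, conf / np.where(total == 0, 1, total), 1.0 / n)
        return proba

    def predict(self, X) -> np.ndarray:
        """Argmax-confidence class per row; ties -> first in class order."""
        conf = self.predict_confidence(X)
        return self.classes_[np.argmax(conf, axis=1)]


@dataclass
class EvaluationReport:
    """Pooled cross-validation confusion matrix with derived metrics.

    Percentages are kept at full precision; ``rounded()`` gives the
    one-decimal reporting view.
    """

    classes: tuple
    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f_measure: np.ndarray
    accuracy: float
    binary_confusion: np.ndarray
    binary_precision: np.ndarray
    binary_recall: np.ndarray
    binary_f_measure: np.ndarray
    binary_accuracy: float

    def rounded(self) -> dict:
        r = lambda a: np.round(np.asarray(a, dtype=float), 1).tolist()
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "precision": r(self.precision),
            "recall": r(self.recall),
            "f_measure": r(self.f_measure),
            "accuracy": round(self.accuracy, 1),
            "binary_confusion": self.binary_confusion.tolist(),
            "binary_precision": r(self.binary_precision),
            "binary_recall": r(self.binary_recall),
            "binary_f_measure": r(self.binary_f_measure),
            "binary_accuracy": round(self.binary_accuracy, 1),
        }


def compute_metrics(confusion: np.ndarray) -> dict:
    """Per-class precision / recall / F-measure and accuracy, as percentages.

    Rows are actual classes, columns predicted.  A zero column sum makes
    that precision undefined: reported as NaN with a warning.
    """
    M = np.asarray(confusion, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(M < 0):
        raise ValueError("confusion matrix entries must be nonnegative")
    total = M.sum()
    if total < 1:
        raise ValueError("confusion matrix must contain at least one count")
    colsum = M.sum(axis=0)
    rowsum = M.sum(axis=1)
    diag = np.diag(M)
    if np.any(colsum == 0):
        warnings.warn("zero column sum: precision undefined for some class", RuntimeWarning)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(colsum > 0, 100.0 * diag / colsum, np.nan)
        recall = np.where(rowsum > 0, 100.0 * diag / rowsum, np.nan)
        denom = precision + recall
        f = np.where(denom > 0, 2.0 * precision * recall / denom, 0.0)
    return {
        "precision": precision,
        "recall": recall,
        "f_measure": f,
        "accuracy": 100.0 * diag.sum() / total,
    }


def collapse_binary(confusion: np.ndarray) -> np.ndarray:
    """Merge anti+pro into one stance category, rows and columns alike.

    Input must be 3x3 in class order (anti, pro, neutral); output order is
    (pro-or-anti, neutral).
    """
    M = np.asarray(confusion)
    if M.shape != (3, 3):
        raise ValueError("expected a 3x3 confusion matrix in order anti/pro/neutral")
    out = np.empty((2, 2), dtype=M.dtype)
    out[0, 0] = M[:2, :2].sum()
    out[0, 1] = M[:2, 2].sum()
    out[1, 0] = M[2, :2].sum()
    out[1, 1] = M[2, 2]
    return out


def _report_from_confusion(classes: tuple, confusion: np.ndarray) -> EvaluationReport:
    m = compute_metrics(confusion)
    bc = collapse_binary(confusion)
    bm = compute_metrics(bc)
    return EvaluationReport(
        classes=classes,
        confusion=confusion,
        precision=m["precision"],
        recall=m["recall"],
        f_measure=m["f_measure"],
        accuracy=m["accuracy"],
        binary_confusion=bc,
        binary_precision=bm["precision"],
        binary_recall=bm["recall"],
        binary_f_measure=bm["f_measure"],
        binary_accuracy=bm["accuracy"],
    )


def cross_validate(
    texts: Sequence[str],
    labels: Sequence[str],
    k: int = 10,
    C: float = 1.0,
    seed: int | None = None,
    per_fold_vocabulary: bool = False,
    vectorizer: TweetVectorizer | None = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation with a pooled confusion matrix.

    Each fold: the training portion is oversampled to class balance, one
    one-vs-all model is trained and applied to the held-out fold; the
    per-fold confusion matrices are summed.  The vocabulary is built once
    on the full corpus by default (matching a preprocess-then-split
    order); ``per_fold_vocabulary=True`` rebuilds it inside each fold.
    """
    labels = np.asarray(labels)
    classes = tuple(c for c in CLASS_ORDER if c in set(labels.tolist()))
    if len(classes) != len(set(labels.tolist())):
        raise ValueError(f"labels must be drawn from {CLASS_ORDER}")
    supports = {c: int(np.sum(labels == c)) for c in classes}
    small = [c for c, n in supports.items() if n < k]
    if small:
        raise ValueError(f"classes smaller than k={k}: {small}")

    vec = vectorizer or TweetVectorizer()
    texts = list(texts)
    if not per_fold_vocabulary:
        X_all = vec.fit(texts).transform(texts)

    idx_of = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        if per_fold_vocabulary:
            fold_vec = TweetVectorizer(
                stopwords=vec.stopwords, extra_stopwords=vec.extra_stopwords
            )
            X_train = fold_vec.fit([texts[i] for i in train_idx]).transform(
                [texts[i] for i in train_idx]
            )
            X_test = fold_vec.transform([texts[i] for i in test_idx])
        else:
            X_train, X_test = X_all[train_idx], X_all[test_idx]
        fold_seed = None if seed is None else (seed + fold) % (2**31)
        clf = StanceClassifier(C=C, random_state=fold_seed).fit(X_train, labels[train_idx])
        pred = clf.predict(X_test)
        for t, p in zip(labels[test_idx], pred):
            confusion[idx_of[t], idx_of[p]] += 1
    return _report_from_confusion(classes, confusion)


def save_model(clf: StanceClassifier, vocab: Vocabulary, path: str | Path) -> None:
    """Serialize a fitted model with its vocabulary as portable JSON."""
    check_is_fitted(clf, "coef_")
    payload = {
        "classes": [str(c) for c in clf.classes_],
        "C": clf.C,
        "vocabulary": vocab.tokens,
        "intercepts": clf.intercept_.tolist(),
        "coefficients": [
            {str(j): float(v) for j, v in zip(np.nonzero(row)[0], row[np.nonzero(row)[0]])}
            for row in clf.coef_
        ],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_model(path: str | Path) -> tuple[StanceClassifier, Vocabulary]:
    """Load a model serialized by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    tokens = payload["vocabulary"]
    vocab = Vocabulary({tok: i for i, tok in enumerate(tokens)})
    clf = StanceClassifier(C=payload["C"])
    clf.classes_ = np.asarray(payload["classes"])
    n = len(tokens)
    coef = np.zeros((len(payload["classes"]), n))
    for i, row in enumerate(payload["coefficients"]):
        for j, v in row.items():
            coef[i, int(j)] = v
    clf.coef_ = coef
    clf.intercept_ = np.asarray(payload["intercepts"], dtype=float)
    clf.n_features_in_ = n
    return clf, vocab
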