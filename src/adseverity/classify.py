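"""Baseline severity classifiers behind one train/predict contract.

Five standard methods — k-nearest neighbours, RBF support-vector
machine, decision tree, linear discriminant analysis, and random
forest — are wrapped with fixed default hyperparameters and a common
stratified 80/20 train/test split.  Labels are the four ordinal
severity classes in fixed order (low, mild, moderate, severe).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .mmse import CLASS_NAMES

__all__ = ["METHODS", "SplitSpec", "Split", "TrainedClassifier", "split", "train", "predict"]

METHODS = ("knn", "svm", "dt", "lda", "rf")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class Split:
    train_idx: np.ndarray
    test_idx: np.ndarray
    X_train: np.ndarray
    X_test: np.ndarray
    y_train: np.ndarray
    y_test: np.ndarray


@dataclass(frozen=True)
class TrainedClassifier:
    method: str
    estimator: object
    classes: tuple[str, ...] = CLASS_NAMES


def split(features: np.ndarray, labels: np.ndarray, spec: SplitSpec | None = None) -> Split:
    """Deterministic (seeded) train/test partition, stratified by default."""
    if spec is None:
        spec = SplitSpec()
    X = np.asarray(features)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must be aligned")
    if spec.stratified:
        _, counts = np.unique(y, return_counts=True)
        if np.any(counts < 2):
            raise ValueError("stratified split needs >= 2 members per class")
    idx = np.arange(X.shape[0])
    tr, te = train_test_split(
        idx, train_size=spec.train_fraction, random_state=spec.seed,
        stratify=y if spec.stratified else None)
    tr, te = np.sort(tr), np.sort(te)
    return Split(tr, te, X[tr], X[te], y[tr], y[te])


def _make_estimator(method: str, hyperparameters: dict | None, seed: int):
    hp = dict(hyperparameters or {})
    if method == "knn":
        return KNeighborsClassifier(**{"n_neighbors": 5, **hp})
    if method == "svm":
        # probability=True so every method exposes per-class scores for ROC
        return SVC(**{"kernel": "rbf", "C": 1.0, "probability": True,
                      "random_state": seed, **hp})
    if method == "dt":
        return DecisionTreeClassifier(**{"criterion": "gini", "random_state": seed, **hp})
    if method == "lda":
        return LinearDiscriminantAnalysis(**{"solver": "lsqr", "shrinkage": "auto", **hp})
    if method == "rf":
        return RandomForestClassifier(**{"n_estimators": 100, "random_state": seed, **hp})
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def train(method: str, train_features: np.ndarray, train_labels: np.ndarray,
          hyperparameters: dict | None = None, seed: int = 0) -> TrainedClassifier:
    """Fit one baseline method; refits with the same seed reproduce predictions."""
    y = np.asarray(train_labels)
    if np.unique(y).size < 2:
        raise ValueError("training needs at least 2 classes present")
    est = _make_estimator(method, hyperparameters, seed)
    est.fit(np.asarray(train_features, dtype=float), y)
    return TrainedClassifier(method, est)


def predict(model: TrainedClassifier, features: np.ndarray,
            return_scores: bool = False):
    """Predicted labels, optionally with per-class probability scores.

    Score columns follow the fixed class order (low, mild, moderate,
    severe); classes absent at training time get score 0.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        X = X.reshape(len(X), -1) if len(X) else X.reshape(0, 1)
    n_expected = getattr(model.estimator, "n_features_in_", None)
    if X.shape[0] == 0:
        labels = np.array([], dtype=int)
        return (labels, np.zeros((0, 4))) if return_scores else labels
    if n_expected is not None and X.shape[1] != n_expected:
        raise ValueError(f"feature dimension {X.shape[1]} != trained {n_expected}")
    labels = model.estimator.predict(X)
    if not return_scores:
        return labels
    proba = model.estimator.predict_proba(X)
    scores = np.zeros((X.shape[0], len(model.classes)))
    for col, cls in enumerate(model.estimator.classes_):
        scores[:, int(cls)] = proba[:, col]
    return labels, scores
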