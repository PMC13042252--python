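"""Five-class sweep classifier and its evaluation utilities.

The estimator maps flattened 12 x k feature matrices to posterior
probabilities over (neutral, hard-linked, soft-linked, hard, soft) via a
small fully connected network with a softmax output, trained by Adam on
categorical cross-entropy.  Training holds out a validation fraction and
applies patience-based early stopping: if ``patience`` consecutive epochs
fail to improve the best validation loss by at least ``min_delta``,
training stops and the weights achieving the minimum validation loss are
restored.

The network is intentionally small — the input is a 132-dimensional
normalized spatial profile, not an image — and any probabilistic
classifier satisfying the same posterior contract could be substituted.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    average_precision_score,
    log_loss,
    precision_recall_curve,
    roc_curve,
)
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from .core import CLASS_LABELS, SWEEP_CLASS_INDICES


@dataclass(frozen=True)
class ClassPosterior:
    """Softmax posterior over the five sweep classes."""

    p_neutral: float
    p_hard_linked: float
    p_soft_linked: float
    p_hard: float
    p_soft: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
            raise ValueError("probabilities must be in [0, 1]")
        if abs(arr.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.p_neutral, self.p_hard_linked, self.p_soft_linked, self.p_hard, self.p_soft]
        )

    @property
    def combined_sweep_prob(self) -> float:
        return self.p_hard + self.p_soft

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ClassPosterior":
        return cls(*(float(v) for v in arr))


def encode_labels(labels) -> np.ndarray:
    """Map class-label strings to indices in the canonical CLASS_LABELS order."""
    lookup = {c: i for i, c in enumerate(CLASS_LABELS)}
    return np.array([lookup[l] for l in labels], dtype=np.int64)


class SweepClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn-style 5-class sweep classifier.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Sizes of the fully connected hidden layers.
    val_fraction : float
        Fraction of the training set held out for early stopping.
    patience : int
        Consecutive epochs without sufficient improvement before stopping.
    min_delta : float
        Minimum decrease of the best validation cross-entropy that counts
        as improvement.
    max_epochs : int
        Hard cap on training epochs.
    random_state : int or None
        Seed for the validation split and weight initialization; fixing it
        makes training fully reproducible (identical epoch-loss trace).
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple = (128, 64),
        val_fraction: float = 0.1,
        patience: int = 5,
        min_delta: float = 0.001,
        max_epochs: int = 200,
        batch_size: int = 32,
        learning_rate_init: float = 1e-3,
        alpha: float = 1e-4,
        random_state: int | None = None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.val_fraction = val_fraction
        self.patience = patience
        self.min_delta = min_delta
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.learning_rate_init = learning_rate_init
        self.alpha = alpha
        self.random_state = random_state

    # -- training -----------------------------------------------------------
    def fit(self, X, y) -> "SweepClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")
        present = set(np.unique(y).tolist())
        if len(present) < 2:
            raise ValueError("training requires at least 2 classes")
        if present <= set(CLASS_LABELS):
            self.classes_ = np.array([c for c in CLASS_LABELS if c in present])
        else:
            self.classes_ = np.unique(y)
        class_index = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([class_index[v] for v in y])
        n_classes = len(self.classes_)

        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(X.shape[0])
        n_val = max(1, int(round(self.val_fraction * X.shape[0])))
        val_ids, train_ids = order[:n_val], order[n_val:]
        X_tr, y_tr = X[train_ids], y_idx[train_ids]
        X_val, y_val = X[val_ids], y_idx[val_ids]
        if len(np.unique(y_tr)) < 2:
            raise ValueError("training split has fewer than 2 classes")

        mlp = MLPClassifier(
            hidden_layer_sizes=self.hidden_layer_sizes,
            batch_size=min(self.batch_size, X_tr.shape[0]),
            learning_rate_init=self.learning_rate_init,
            alpha=self.alpha,
            solver="adam",
            shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        all_classes = np.arange(n_classes)
        history: list[dict] = []
        best_loss = np.inf
        best_state = None
        stale = 0
        for epoch in range(self.max_epochs):
            mlp.partial_fit(X_tr, y_tr, classes=all_classes)
            val_loss = log_loss(y_val, mlp.predict_proba(X_val), labels=all_classes)
            train_loss = log_loss(y_tr, mlp.predict_proba(X_tr), labels=all_classes)
            history.append(
                {"epoch": epoch, "train_loss": float(train_loss), "val_loss": float(val_loss)}
            )
            improved = best_loss - val_loss >= self.min_delta
            if val_loss < best_loss:
                best_loss = val_loss
                best_state = (
                    copy.deepcopy(mlp.coefs_),
                    copy.deepcopy(mlp.intercepts_),
                )
            if improved:
                stale = 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        mlp.coefs_, mlp.intercepts_ = best_state
        self.net_ = mlp
        self.history_ = history
        self.best_val_loss_ = float(best_loss)
        self.n_features_in_ = X.shape[1]
        return self

    # -- inference ----------------------------------------------------------
    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self.net_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def train(
    X,
    y,
    val_fraction: float = 0.1,
    patience: int = 5,
    min_delta: float = 0.001,
    architecture_config: dict | None = None,
    random_state: int | None = None,
) -> SweepClassifier:
    """Train a sweep classifier with the standard early-stopping rule."""
    kwargs = dict(architecture_config or {})
    clf = SweepClassifier(
        val_fraction=val_fraction,
        patience=patience,
        min_delta=min_delta,
        random_state=random_state,
        **kwargs,
    )
    return clf.fit(X, y)


def predict(model: SweepClassifier, features) -> ClassPosterior:
    """Posterior for a single feature matrix (flattened or 2-D)."""
    arr = np.asarray(features, dtype=float).ravel()
    probs = model.predict_proba(arr[None, :])[0]
    full = np.zeros(len(CLASS_LABELS))
    for cls, p in zip(model.classes_, probs):
        full[CLASS_LABELS.index(cls)] = p
    return ClassPosterior.from_array(full / full.sum())


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """5x5 confusion counts at a combined-sweep-probability threshold.

    ``counts[i, j]`` is the number of test examples of true class i
    assigned to class j; examples whose argmax is a sweep class but whose
    combined sweep probability falls below the threshold are counted in
    ``omitted[i]`` (treated as uncertain) instead of being assigned.
    """

    threshold: float | None
    counts: np.ndarray
    omitted: np.ndarray

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1) + self.omitted

    def rate(self, true_label: str, assigned_label: str) -> float:
        """P(assigned | true) over non-omitted assignments."""
        i = CLASS_LABELS.index(true_label)
        j = CLASS_LABELS.index(assigned_label)
        denom = self.counts[i].sum()
        return float(self.counts[i, j] / denom) if denom else 0.0


def _posterior_array(posteriors) -> np.ndarray:
    arr = np.asarray(
        [p.as_array() if isinstance(p, ClassPosterior) else p for p in posteriors],
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[1] != len(CLASS_LABELS):
        raise ValueError("posteriors must be n x 5")
    return arr


def confusion_at_threshold(posteriors, truths, threshold: float | None) -> ConfusionMatrix:
    """Confusion matrix under the combined-sweep-probability rule."""
    arr = _posterior_array(posteriors)
    t_idx = encode_labels(truths)
    if arr.shape[0] != t_idx.shape[0]:
        raise ValueError("posteriors/truths length mismatch")
    n = len(CLASS_LABELS)
    counts = np.zeros((n, n), dtype=np.int64)
    omitted = np.zeros(n, dtype=np.int64)
    assigned = arr.argmax(axis=1)
    combined = arr[:, SWEEP_CLASS_INDICES[0]] + arr[:, SWEEP_CLASS_INDICES[1]]
    for true, pred, comb in zip(t_idx, assigned, combined):
        if (
            threshold is not None
            and pred in SWEEP_CLASS_INDICES
            and comb < threshold
        ):
            omitted[true] += 1
        else:
            counts[true, pred] += 1
    return ConfusionMatrix(threshold=threshold, counts=counts, omitted=omitted)


def binary_sweep_curves(posteriors, truths):
    """ROC and PR curves for sweep (hard/soft) vs unselected (rest).

    The score is the combined hard+soft posterior.  Returns
    (roc_points, pr_points, auc, average_precision) with roc_points an
    array of (fpr, tpr) rows and pr_points an array of (recall, precision)
    rows.
    """
    arr = _posterior_array(posteriors)
    t_idx = encode_labels(truths)
    score = arr[:, SWEEP_CLASS_INDICES[0]] + arr[:, SWEEP_CLASS_INDICES[1]]
    positive = np.isin(t_idx, SWEEP_CLASS_INDICES).astype(int)
    if positive.all() or not positive.any():
        raise ValueError("need both sweep and unselected truths")
    fpr, tpr, _ = roc_curve(positive, score)
    auc = float(np.trapezoid(tpr, fpr))
    precision, recall, _ = precision_recall_curve(positive, score)
    ap = float(average_precision_score(positive, score))
    roc_points = np.column_stack([fpr, tpr])
    pr_points = np.column_stack([recall, precision])
    return roc_points, pr_points, auc, ap
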