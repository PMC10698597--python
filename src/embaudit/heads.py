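"""Multilabel classification heads trained on frozen embeddings.

Three fixed head capacities probe how much task signal a frozen feature
representation carries: a single fully connected layer (``linear``) and two
multilayer perceptrons with three and five hidden layers (``mlp3``,
``mlp5``).  Heads consume embedding rows as-is — the frozen-backbone
contract is absolute, no operation alters the inputs — and produce
independent per-label probabilities (per-label binary cross-entropy loss).

Model selection is validation-based: training tracks mean validation AUC
over the non-degenerate labels and the parameter state achieving the best
value is kept.  The linear head is a convex per-label logistic regression,
so it is fit once to convergence; the MLPs are optimized in short epochs
with snapshotting.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = ["HeadSpec", "ClassificationHead", "train_head", "predict", "save_head", "load_head"]

_HIDDEN_LAYERS = {"linear": 0, "mlp3": 3, "mlp5": 5}


@dataclass(frozen=True)
class HeadSpec:
    """Architecture of a classification head."""

    name: str  # linear | mlp3 | mlp5
    hidden_width: int = 256

    def __post_init__(self) -> None:
        if self.name not in _HIDDEN_LAYERS:
            raise ValueError(f"head name must be one of {sorted(_HIDDEN_LAYERS)}")
        if self.hidden_width < 1:
            raise ValueError("hidden_width must be positive")

    @property
    def hidden_layers(self) -> int:
        return _HIDDEN_LAYERS[self.name]


class ClassificationHead(ClassifierMixin, BaseEstimator):
    """Multilabel probabilistic head over frozen features.

    Parameters
    ----------
    name : {"linear", "mlp3", "mlp5"}
        Head capacity: 0, 3, or 5 hidden layers.
    hidden_width : int, default=256
        Width of each hidden layer (MLP heads only).
    max_epochs : int, default=60
        Optimization budget for MLP heads, in snapshot epochs of
        ``iters_per_epoch`` Adam passes each.
    iters_per_epoch : int, default=5
    learning_rate : float, default=1e-3
    patience : int, default=10
        Snapshot epochs without validation improvement before stopping.
    random_state : int, default=0

    Attributes
    ----------
    selection_metric_ : float
        Best mean validation AUC over non-degenerate labels.
    excluded_labels_ : list of int
        Label columns constant in training, excluded from the selection
        metric (a warning is emitted for each).
    """

    def __init__(
        self,
        name: str = "linear",
        hidden_width: int = 256,
        max_epochs: int = 60,
        iters_per_epoch: int = 5,
        learning_rate: float = 1e-3,
        patience: int = 10,
        random_state: int = 0,
    ):
        self.name = name
        self.hidden_width = hidden_width
        self.max_epochs = max_epochs
        self.iters_per_epoch = iters_per_epoch
        self.learning_rate = learning_rate
        self.patience = patience
        self.random_state = random_state

    # -- helpers -------------------------------------------------------
    @staticmethod
    def _validate_xy(X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y)
        if Y.ndim == 1:
            Y = Y[:, None]
        if X.shape[0] != Y.shape[0]:
            raise ValueError("feature and label row counts differ")
        if not np.isin(Y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        return X, Y.astype(int)

    def _mean_val_auc(self, proba, Y_val, active):
        aucs = []
        for j in active:
            if len(np.unique(Y_val[:, j])) < 2:
                continue
            aucs.append(roc_auc_score(Y_val[:, j], proba[:, j]))
        return float(np.mean(aucs)) if aucs else np.nan

    # -- estimator API -------------------------------------------------
    def fit(self, X, Y, X_val=None, Y_val=None):
        spec = HeadSpec(self.name, self.hidden_width)
        X, Y = self._validate_xy(X, Y)
        if X_val is None:
            X_val, Y_val = X, Y
        else:
            X_val, Y_val = self._validate_xy(X_val, Y_val)
        n_labels = Y.shape[1]

        self.excluded_labels_ = [j for j in range(n_labels) if len(np.unique(Y[:, j])) < 2]
        for j in self.excluded_labels_:
            warnings.warn(
                f"label column {j} is constant in training; excluded from model selection",
                UserWarning,
            )
        active = [j for j in range(n_labels) if j not in self.excluded_labels_]

        if spec.hidden_layers == 0:
            self.models_ = []
            for j in range(n_labels):
                if j in self.excluded_labels_:
                    self.models_.append(float(Y[:, j].mean()))  # constant-rate fallback
                    continue
                lr = LogisticRegression(max_iter=2000, random_state=self.random_state)
                lr.fit(X, Y[:, j])
                self.models_.append(lr)
            self.mlp_ = None
            self.selection_metric_ = self._mean_val_auc(
                self._proba_from_models(X_val), Y_val, active
            )
            self.training_curve_ = [self.selection_metric_]
        else:
            mlp = MLPClassifier(
                hidden_layer_sizes=(spec.hidden_width,) * spec.hidden_layers,
                activation="relu",
                solver="adam",
                learning_rate_init=self.learning_rate,
                max_iter=self.iters_per_epoch,
                warm_start=True,
                random_state=self.random_state,
                tol=0.0,
            )
            best = (-np.inf, None, None)
            curve = []
            stale = 0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                for _ in range(self.max_epochs):
                    mlp.fit(X, Y)
                    score = self._mean_val_auc(mlp.predict_proba(X_val), Y_val, active)
                    curve.append(score)
                    if np.isnan(score):
                        break
                    if score > best[0]:
                        best = (
                            score,
                            copy.deepcopy(mlp.coefs_),
                            copy.deepcopy(mlp.intercepts_),
                        )
                        stale = 0
                    else:
                        stale += 1
                        if stale >= self.patience:
                            break
            if best[1] is not None:
                mlp.coefs_, mlp.intercepts_ = best[1], best[2]
            self.mlp_ = mlp
            self.models_ = None
            self.selection_metric_ = best[0] if np.isfinite(best[0]) else np.nan
            self.training_curve_ = curve
        self.n_features_in_ = X.shape[1]
        self.n_labels_ = n_labels
        self.spec_ = spec
        return self

    def _proba_from_models(self, X):
        cols = []
        for m in self.models_:
            if isinstance(m, float):
                cols.append(np.full(X.shape[0], m))
            else:
                cols.append(m.predict_proba(X)[:, 1])
        return np.column_stack(cols)

    def predict_proba(self, X):
        """Per-label probabilities, shape (n_rows, n_labels), in [0, 1]."""
        check_is_fitted(self, "n_labels_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got shape {X.shape}"
            )
        if self.mlp_ is not None:
            proba = self.mlp_.predict_proba(X)
            if proba.ndim == 1 or proba.shape[1] != self.n_labels_:
                # sklearn returns (n, 2) for a single binary label
                proba = np.atleast_2d(proba)[:, -1][:, None]
            return np.clip(proba, 0.0, 1.0)
        return np.clip(self._proba_from_models(X), 0.0, 1.0)

    def predict(self, X):
        return (self.predict_proba(X) > 0.5).astype(int)

    def training_log_loss(self, X, Y):
        """Mean per-label binary cross-entropy of current parameters."""
        X, Y = self._validate_xy(X, Y)
        proba = np.clip(self.predict_proba(X), 1e-12, 1 - 1e-12)
        losses = [log_loss(Y[:, j], proba[:, j], labels=[0, 1]) for j in range(Y.shape[1])]
        return float(np.mean(losses))


def train_head(train_features, train_labels, val_features, val_labels, spec: HeadSpec, seed: int = 0, **kwargs) -> ClassificationHead:
    """Train one head with validation-based model selection."""
    head = ClassificationHead(
        name=spec.name, hidden_width=spec.hidden_width, random_state=seed, **kwargs
    )
    return head.fit(train_features, train_labels, val_features, val_labels)


def predict(head: ClassificationHead, features) -> np.ndarray:
    """Per-label probabilities for ``features`` from a trained head."""
    return head.predict_proba(features)


def save_head(head: ClassificationHead, path) -> None:
    joblib.dump(head, path)


def load_head(path) -> ClassificationHead:
    return joblib.load(path)
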