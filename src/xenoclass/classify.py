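"""Feature-based cell classifier.

A small dense network maps the 484-value descriptor to class probabilities
(human vs mouse by default, any label set in general). Features are z-scored
with statistics fitted on the training data (zero-variance features are masked
to 0 rather than dropped, preserving the vector length); the network is
484 -> 128 -> 64 -> n_classes with ReLU hidden units, softmax output,
cross-entropy loss, and early stopping on a 10% validation split.

:class:`CellClassifier` follows the scikit-learn estimator contract
(``fit`` / ``predict`` / ``predict_proba`` / ``get_params``), so it composes
with sklearn pipelines and model selection.
"""

from __future__ import annotations

import json
import os

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted

from .catalog import catalog_names

__all__ = ["CellClassifier", "balance_classes", "train_classifier"]


def balance_classes(features, labels, seed: int = 0):
    """Randomly downsample every class to the minority-class count.

    Returns (features_subset, labels_subset, selected_indices); the selection
    is seeded and reproducible. Balancing gives each class equal influence on
    training, mirroring the study design where the majority host-cell class
    was subsampled to match the xenografted class.
    """
    X = np.asarray(features)
    y = np.asarray(labels)
    if len(X) != len(y):
        raise ValueError("features and labels length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if (counts == 0).any() or len(classes) < 2:
        raise ValueError("need at least 2 non-empty classes")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(np.sort(idx))
    sel = np.sort(np.concatenate(keep))
    return X[sel], y[sel], sel


class CellClassifier(ClassifierMixin, BaseEstimator):
    """Dense-network classifier over the per-cell feature descriptor.

    Parameters
    ----------
    hidden_layer_sizes : tuple
        Hidden layer widths (default (128, 64)).
    alpha : float
        L2 penalty; the regularizer used in place of dropout.
    max_iter, early_stopping, validation_fraction, n_iter_no_change :
        Training schedule; early stopping monitors a held-out 10% split.
    random_state : int
        Seed for weight initialization, shuffling and the validation split.

    Attributes (after fit)
    ----------------------
    classes_ : ndarray of class labels.
    mean_, scale_ : per-feature normalization statistics.
    zero_variance_mask_ : features constant in training, forced to 0.
    net_ : the fitted dense network.
    feature_catalog_hash_ : hash of the feature catalog the model expects.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (128, 64),
        alpha: float = 1e-3,
        learning_rate_init: float = 1e-3,
        max_iter: int = 500,
        early_stopping: bool = True,
        validation_fraction: float = 0.1,
        n_iter_no_change: int = 20,
        random_state: int = 0,
    ) -> None:
        self.hidden_layer_sizes = hidden_layer_sizes
        self.alpha = alpha
        self.learning_rate_init = learning_rate_init
        self.max_iter = max_iter
        self.early_stopping = early_stopping
        self.validation_fraction = validation_fraction
        self.n_iter_no_change = n_iter_no_change
        self.random_state = random_state

    def fit(self, X, y, feature_names=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_cells, n_features)")
        if not np.isfinite(X).all():
            raise ValueError("features must be finite")
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class")
        self.n_features_in_ = X.shape[1]
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.zero_variance_mask_ = sd == 0
        self.scale_ = np.where(self.zero_variance_mask_, 1.0, sd)
        if feature_names is None:
            feature_names = catalog_names()
        self.feature_catalog_hash_ = _names_hash(feature_names)
        self.net_ = MLPClassifier(
            hidden_layer_sizes=self.hidden_layer_sizes,
            activation="relu",
            solver="adam",
            alpha=self.alpha,
            learning_rate_init=self.learning_rate_init,
            max_iter=self.max_iter,
            early_stopping=self.early_stopping,
            validation_fraction=self.validation_fraction,
            n_iter_no_change=self.n_iter_no_change,
            random_state=self.random_state,
        )
        self.net_.fit(self._transform(X), y)
        self.classes_ = self.net_.classes_
        return self

    def _transform(self, X: np.ndarray) -> np.ndarray:
        Xn = (X - self.mean_) / self.scale_
        Xn[:, self.zero_variance_mask_] = 0.0
        return Xn

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return X

    def predict_proba(self, X) -> np.ndarray:
        return self.net_.predict_proba(self._transform(self._check_X(X)))

    def predict(self, X) -> np.ndarray:
        return self.net_.predict(self._transform(self._check_X(X)))

    def check_compatible(self, feature_names) -> None:
        """Raise when a feature table was built under a different catalog."""
        check_is_fitted(self, "feature_catalog_hash_")
        if _names_hash(feature_names) != self.feature_catalog_hash_:
            raise ValueError(
                "feature table is incompatible with this model "
                "(feature catalog hash mismatch)"
            )

    # -- serialization: a directory with JSON metadata + portable weights ----

    def save(self, path) -> None:
        check_is_fitted(self, "net_")
        os.makedirs(path, exist_ok=True)
        meta = {
            "classes": [str(c) for c in self.classes_],
            "feature_catalog_hash": self.feature_catalog_hash_,
            "n_features": int(self.n_features_in_),
            "normalization": {
                "mean": self.mean_.tolist(),
                "scale": self.scale_.tolist(),
                "zero_variance_mask": self.zero_variance_mask_.astype(int).tolist(),
            },
            "params": self.get_params(),
        }
        meta["params"]["hidden_layer_sizes"] = list(self.hidden_layer_sizes)
        with open(os.path.join(path, "model.json"), "w") as fh:
            json.dump(meta, fh, indent=1)
        joblib.dump(self.net_, os.path.join(path, "weights.joblib"))

    @classmethod
    def load(cls, path) -> "CellClassifier":
        with open(os.path.join(path, "model.json")) as fh:
            meta = json.load(fh)
        params = dict(meta["params"])
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
        model = cls(**params)
        model.n_features_in_ = meta["n_features"]
        model.mean_ = np.array(meta["normalization"]["mean"])
        model.scale_ = np.array(meta["normalization"]["scale"])
        model.zero_variance_mask_ = np.array(
            meta["normalization"]["zero_variance_mask"], dtype=bool
        )
        model.feature_catalog_hash_ = meta["feature_catalog_hash"]
        model.net_ = joblib.load(os.path.join(path, "weights.joblib"))
        model.classes_ = model.net_.classes_
        return model


def _names_hash(names) -> str:
    import hashlib

    return hashlib.sha256(json.dumps(list(names)).encode()).hexdigest()


def train_classifier(features, labels, seed: int = 0, **params) -> CellClassifier:
    """Fit a :class:`CellClassifier`; thin functional wrapper."""
    import pandas as pd

    feature_names = None
    if isinstance(features, pd.DataFrame):
        feature_names = list(features.columns)
    clf = CellClassifier(random_state=seed, **params)
    return clf.fit(np.asarray(features, dtype=float), labels, feature_names)
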