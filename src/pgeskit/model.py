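"""Random-forest snippet classifier.

A forest of 501 trees (bootstrap samples, sqrt-of-feature-count random
feature subsetting at each split) classifies whether a 10-s snippet contains
the end of PGES. The snippet score is the fraction of trees voting positive,
which is what the ROC analysis thresholds.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import PersistenceError, SchemaError, TrainingError

#: Default ensemble size, selected by cross-validation on the training set.
DEFAULT_N_TREES = 501

_FORMAT_VERSION = 1


class PgesEndClassifier:
    """Random-forest classifier for end-of-PGES snippets (sklearn-style).

    Parameters
    ----------
    n_trees : int
        Number of trees in the forest (default 501). All other tree
        hyperparameters keep the library defaults (full depth,
        sqrt(n_features) candidate features per split).
    random_state : int or None
        Seed controlling bootstrap samples and feature subsetting.
    threshold : float
        Operating point for hard classification (default 0.5).

    Attributes (after :meth:`fit`)
    ------------------------------
    forest_ : RandomForestClassifier
    feature_names_ : list of str
        Exact ordered feature names the model was fitted on; prediction
        refuses tables whose names or order differ.
    train_meta_ : dict
        Seed and dataset fingerprint (row/column counts, label counts).
    """

    def __init__(self, n_trees: int = DEFAULT_N_TREES,
                 random_state: Optional[int] = None, threshold: float = 0.5):
        self.n_trees = n_trees
        self.random_state = random_state
        self.threshold = threshold

    # -- sklearn plumbing ---------------------------------------------------

    def get_params(self, deep: bool = True):
        return {"n_trees": self.n_trees, "random_state": self.random_state,
                "threshold": self.threshold}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting ------------------------------------------------------------

    @staticmethod
    def _coerce(X):
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), [str(c) for c in X.columns]
        arr = np.asarray(X, dtype=float)
        return arr, [f"x{i}" for i in range(arr.shape[1])]

    def fit(self, X, y):
        arr, names = self._coerce(X)
        y = np.asarray(y).astype(int)
        if arr.shape[0] != y.shape[0]:
            raise TrainingError("X and y have different numbers of rows")
        bad = ~np.isfinite(arr)
        if bad.any():
            col = names[int(np.argwhere(bad.any(axis=0)).ravel()[0])]
            raise TrainingError(f"non-finite values in feature column {col!r}")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise TrainingError("training labels contain a single class")
        if counts.min() < 2:
            raise TrainingError("need at least 2 rows per class")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees, random_state=self.random_state, n_jobs=1
        ).fit(arr, y)
        self.feature_names_ = names
        self.classes_ = self.forest_.classes_
        self.train_meta_ = {
            "seed": self.random_state,
            "n_rows": int(arr.shape[0]),
            "n_features": int(arr.shape[1]),
            "n_positive": int((y == 1).sum()),
            "n_negative": int((y == 0).sum()),
        }
        return self

    # -- prediction ---------------------------------------------------------

    def _validate(self, X) -> np.ndarray:
        if not hasattr(self, "forest_"):
            raise TrainingError("classifier is not fitted")
        arr, names = self._coerce(X)
        if isinstance(X, pd.DataFrame) and names != self.feature_names_:
            raise SchemaError(
                "feature names/order differ from those the model was fitted on"
            )
        if arr.shape[1] != len(self.feature_names_):
            raise SchemaError(
                f"expected {len(self.feature_names_)} features, got {arr.shape[1]}"
            )
        return arr

    def predict_score(self, X) -> np.ndarray:
        """Fraction of trees voting positive, one score in [0, 1] per row."""
        arr = self._validate(X)
        if arr.shape[0] == 0:
            return np.zeros(0)
        pos = list(self.forest_.classes_).index(1)
        votes = np.zeros(arr.shape[0])
        for tree in self.forest_.estimators_:
            votes += (tree.predict(arr) == self.forest_.classes_[pos])
        return votes / len(self.forest_.estimators_)

    def predict_proba(self, X) -> np.ndarray:
        s = self.predict_score(X)
        return np.column_stack([1 - s, s])

    def predict(self, X) -> np.ndarray:
        return (self.predict_score(X) >= self.threshold).astype(int)

    def score(self, X, y) -> float:
        return float((self.predict(X) == np.asarray(y).astype(int)).mean())

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Persist as a single versioned binary with an embedded JSON header."""
        if not hasattr(self, "forest_"):
            raise TrainingError("cannot save an unfitted classifier")
        header = json.dumps({
            "format_version": _FORMAT_VERSION,
            "feature_names": self.feature_names_,
            "n_trees": self.n_trees,
            "train_meta": self.train_meta_,
        })
        joblib.dump({"format_version": _FORMAT_VERSION, "header": header,
                     "estimator": self}, path)

    @classmethod
    def load(cls, path) -> "PgesEndClassifier":
        path = Path(path)
        if not path.exists():
            raise PersistenceError(f"no such model file: {path}")
        try:
            payload = joblib.load(path)
        except Exception as exc:
            raise PersistenceError(f"cannot read model file {path}: {exc}") from exc
        if not isinstance(payload, dict) or "format_version" not in payload:
            raise PersistenceError(f"{path} is not a pgeskit model file")
        if payload["format_version"] != _FORMAT_VERSION:
            raise PersistenceError(
                f"unknown model format version {payload['format_version']!r}"
            )
        est = payload["estimator"]
        if not isinstance(est, cls):
            raise PersistenceError(f"{path} does not contain a {cls.__name__}")
        return est


# ---------------------------------------------------------------------------
# Thin functional wrappers


def train(features, labels, n_trees: int = DEFAULT_N_TREES,
          rng_seed: Optional[int] = None) -> PgesEndClassifier:
    """Fit a :class:`PgesEndClassifier` on a feature table."""
    return PgesEndClassifier(n_trees=n_trees, random_state=rng_seed).fit(
        features, labels
    )


def predict_score(m: PgesEndClassifier, features) -> np.ndarray:
    return m.predict_score(features)


def save(m: PgesEndClassifier, path) -> None:
    m.save(path)


def load(path) -> PgesEndClassifier:
    return PgesEndClassifier.load(path)
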