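"""Gradient-boosted tree classification of reduced pair features.

The default classifier is LightGBM with 500 boosting rounds, seed 1 and
library defaults otherwise; any object satisfying the small fit/predict
protocol below can stand in for it, so alternative classifiers can be
benchmarked without changing the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np


@dataclass(frozen=True)
class ClassifierConfig:
    """Boosting configuration; ``extra_params`` passes through verbatim."""

    n_iterations: int = 500
    seed: int = 1
    extra_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class PredictionSet:
    """Interaction probabilities plus 0.5-thresholded hard labels."""

    probabilities: np.ndarray
    pair_ids: list | None = None

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.size and (
            self.probabilities.min() < 0 or self.probabilities.max() > 1
        ):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def hard_labels(self) -> np.ndarray:
        return (self.probabilities >= 0.5).astype(np.int64)

    def __len__(self) -> int:
        return self.probabilities.shape[0]


@runtime_checkable
class ClassifierLike(Protocol):
    """Anything with this surface can replace the default booster."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ClassifierLike": ...

    def predict_proba(self, X: np.ndarray) -> np.ndarray: ...


class LightGBMClassifier:
    """Thin wrapper fixing the documented defaults around lightgbm."""

    def __init__(self, config: ClassifierConfig | None = None):
        self.config = config or ClassifierConfig()
        self._model = None
        self.n_features_: int | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LightGBMClassifier":
        import lightgbm as lgb

        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).ravel()
        if X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains non-finite values")
        if np.unique(y).size < 2:
            raise ValueError("training requires both classes present")
        params = dict(
            objective="binary",
            n_estimators=self.config.n_iterations,
            random_state=self.config.seed,
            verbosity=-1,
        )
        params.update(self.config.extra_params)
        self._model = lgb.LGBMClassifier(**params).fit(X, y)
        self.n_features_ = X.shape[1]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValueError(
                f"expected n x {self.n_features_} features, got {X.shape}"
            )
        if X.shape[0] == 0:
            return np.empty(0)
        return self._model.predict_proba(X)[:, 1]

    @property
    def feature_importances_(self) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("classifier is not fitted")
        return self._model.feature_importances_

    def booster_params(self) -> dict:
        """The exact parameter set in effect, for archive logging."""
        if self._model is None:
            raise RuntimeError("classifier is not fitted")
        return self._model.get_params()


def fit_classifier(
    features, labels: np.ndarray | None = None,
    config: ClassifierConfig | None = None,
    model: ClassifierLike | None = None,
):
    """Fit the (pluggable) classifier on a ReducedSet or a plain matrix."""
    if labels is None:
        X, y = features.hidden_states, features.labels
        if y is None:
            raise ValueError("ReducedSet carries no labels")
    else:
        X, y = features, labels
    clf = model if model is not None else LightGBMClassifier(config)
    return clf.fit(np.asarray(X), np.asarray(y))


def predict(classifier: ClassifierLike, features, pair_ids=None) -> PredictionSet:
    """Probabilities for a ReducedSet or matrix; deterministic given the model."""
    X = features.hidden_states if hasattr(features, "hidden_states") else features
    return PredictionSet(classifier.predict_proba(np.asarray(X)), pair_ids=pair_ids)
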