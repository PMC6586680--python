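"""Pluggable suitability learners.

The consensus model treats individual distribution-model algorithms as
interchangeable probabilistic scorers: anything exposing scikit-learn's
``fit(X, y)`` / ``predict_proba(X)`` contract (with classes {0, 1}) can be
registered as a :class:`Learner`. The default registry covers the common
algorithm families — a linear logistic model, a flexible polynomial
variant, a tree ensemble, a boosted ensemble, a nearest-neighbour scorer
and a distance-to-niche-centroid scorer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler


class NicheCentroidScorer:
    """Suitability from standardised distance to the presence centroid.

    Fits the mean of the presence rows and per-feature scales from all
    rows; scores a row as exp(-d^2/2) where d^2 is the mean squared
    standardised distance to that centroid. A deliberately simple,
    envelope-style scorer in the spirit of climatic-envelope algorithms.
    """

    classes_ = np.array([0, 1])

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.any(y == 1):
            raise ValueError("no presence rows to fit a niche centroid")
        self.centroid_ = X[y == 1].mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        z = (X - self.centroid_) / self.scale_
        p = np.exp(-0.5 * np.mean(z * z, axis=1))
        return np.column_stack([1.0 - p, p])


@dataclass(frozen=True)
class Learner:
    """A named factory producing a fresh estimator for a given seed."""

    name: str
    factory: Callable[[int], Any]

    def build(self, seed: int):
        return self.factory(seed)


def predict_presence_probability(estimator, X) -> np.ndarray:
    """Column of ``predict_proba`` corresponding to class 1."""
    proba = estimator.predict_proba(X)
    classes = list(np.asarray(estimator.classes_).tolist())
    return np.clip(proba[:, classes.index(1)], 0.0, 1.0)


def default_learners() -> list[Learner]:
    """The default registry of six learner types."""
    return [
        Learner("logistic", lambda seed: make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=1000))),
        Learner("poly_logistic", lambda seed: make_pipeline(
            StandardScaler(), PolynomialFeatures(degree=2, include_bias=False),
            LogisticRegression(max_iter=2000))),
        Learner("random_forest", lambda seed: RandomForestClassifier(
            n_estimators=150, min_samples_leaf=2, random_state=seed, n_jobs=1)),
        Learner("gradient_boosting", lambda seed: GradientBoostingClassifier(
            random_state=seed)),
        Learner("knn", lambda seed: make_pipeline(
            StandardScaler(), KNeighborsClassifier(n_neighbors=15))),
        Learner("niche_centroid", lambda seed: NicheCentroidScorer()),
    ]
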