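"""Imbalance-aware ensemble classifiers.

Implementations of four resampling ensembles for rare-event binary
classification, with the scikit-learn ``fit`` / ``predict_proba``
estimator API:

* :class:`EasyEnsembleClassifier` — boosted learners (AdaBoost) trained on
  multiple balanced undersamples of the majority class, averaged.
* :class:`BalancedBaggingClassifier` — bagged decision trees, each on a
  balanced bootstrap.
* :class:`BalancedRandomForestClassifier` — a random forest whose trees
  each see a class-balanced bootstrap.
* :class:`RUSBoostClassifier` — AdaBoost (SAMME) with random undersampling
  of the majority class at every boosting round.

All draw their subsamples down to the minority-class size, so individual
members train on small balanced sets and the ensemble recovers stability
by averaging.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "EasyEnsembleClassifier",
    "BalancedBaggingClassifier",
    "BalancedRandomForestClassifier",
    "RUSBoostClassifier",
]


def _class_indices(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the minority and majority class (ties → class 1 minority)."""
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"expected two classes, got {classes.tolist()}")
    if counts[1] <= counts[0]:
        minority, majority = classes[1], classes[0]
    else:
        minority, majority = classes[0], classes[1]
    return np.flatnonzero(y == minority), np.flatnonzero(y == majority)


class _ResampleEnsembleBase(BaseEstimator, ClassifierMixin):
    """Shared machinery: fit members on resampled index sets, average probs."""

    def __init__(self, n_estimators: int = 10, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def _make_member(self, seed: int):  # pragma: no cover - abstract
        raise NotImplementedError

    def _sample_indices(self, rng, idx_min, idx_maj) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        idx_min, idx_maj = _class_indices(y)
        rng = np.random.default_rng(self.random_state)
        self.estimators_ = []
        for _ in range(self.n_estimators):
            idx = self._sample_indices(rng, idx_min, idx_maj)
            member = self._make_member(int(rng.integers(0, 2**31 - 1)))
            member.fit(X[idx], y[idx])
            self.estimators_.append(member)
        return self

    def _member_proba(self, member, X) -> np.ndarray:
        """Member probabilities aligned onto self.classes_ columns."""
        p = member.predict_proba(X)
        out = np.zeros((X.shape[0], self.classes_.size))
        for j, c in enumerate(member.classes_):
            out[:, np.searchsorted(self.classes_, c)] = p[:, j]
        return out

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        proba = np.zeros((X.shape[0], self.classes_.size))
        for member in self.estimators_:
            proba += self._member_proba(member, X)
        proba /= len(self.estimators_)
        return proba

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class EasyEnsembleClassifier(_ResampleEnsembleBase):
    """Average of AdaBoost learners, each on a balanced undersample.

    Each member sees every minority-class case plus an equal-sized uniform
    draw (without replacement) from the majority class, and boosts
    ``n_boost`` depth-1 trees on it.
    """

    def __init__(
        self,
        n_estimators: int = 10,
        n_boost: int = 10,
        random_state: int | None = None,
    ):
        super().__init__(n_estimators=n_estimators, random_state=random_state)
        self.n_boost = n_boost

    def _make_member(self, seed: int):
        return AdaBoostClassifier(n_estimators=self.n_boost, random_state=seed)

    def _sample_indices(self, rng, idx_min, idx_maj):
        take = rng.choice(idx_maj, size=idx_min.size, replace=False)
        return np.concatenate([idx_min, take])


class BalancedBaggingClassifier(_ResampleEnsembleBase):
    """Bagged decision trees on balanced bootstraps (both classes resampled)."""

    def _make_member(self, seed: int):
        return DecisionTreeClassifier(random_state=seed)

    def _sample_indices(self, rng, idx_min, idx_maj):
        k = idx_min.size
        return np.concatenate(
            [rng.choice(idx_min, size=k, replace=True),
             rng.choice(idx_maj, size=k, replace=True)]
        )


class BalancedRandomForestClassifier(_ResampleEnsembleBase):
    """Random forest with a class-balanced bootstrap per tree."""

    def __init__(self, n_estimators: int = 100, random_state: int | None = None):
        super().__init__(n_estimators=n_estimators, random_state=random_state)

    def _make_member(self, seed: int):
        return DecisionTreeClassifier(max_features="sqrt", random_state=seed)

    def _sample_indices(self, rng, idx_min, idx_maj):
        k = idx_min.size
        return np.concatenate(
            [rng.choice(idx_min, size=k, replace=True),
             rng.choice(idx_maj, size=k, replace=True)]
        )


class RUSBoostClassifier(BaseEstimator, ClassifierMixin):
    """SAMME boosting with per-round random undersampling.

    At each boosting round the majority class is uniformly undersampled to
    the minority size; the weak learner (a depth-1 tree) is fitted on that
    balanced subset with the current boosting weights, while the weighted
    error and weight update use the full training set. Class probabilities
    are the estimator-weight-normalised average of member probabilities.
    """

    def __init__(self, n_estimators: int = 50, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        idx_min, idx_maj = _class_indices(y)
        rng = np.random.default_rng(self.random_state)
        n = y.size
        w = np.full(n, 1.0 / n)
        self.estimators_: list[DecisionTreeClassifier] = []
        self.estimator_weights_: list[float] = []
        for _ in range(self.n_estimators):
            take = rng.choice(idx_maj, size=idx_min.size, replace=False)
            idx = np.concatenate([idx_min, take])
            stump = DecisionTreeClassifier(
                max_depth=1, random_state=int(rng.integers(0, 2**31 - 1))
            )
            stump.fit(X[idx], y[idx], sample_weight=w[idx])
            miss = stump.predict(X) != y
            err = float(w[miss].sum() / w.sum())
            if err <= 0:
                self.estimators_.append(stump)
                self.estimator_weights_.append(10.0)  # effectively perfect member
                break
            if err >= 0.5:
                if not self.estimators_:
                    self.estimators_.append(stump)
                    self.estimator_weights_.append(1e-6)
                break
            alpha = float(np.log((1.0 - err) / err))
            self.estimators_.append(stump)
            self.estimator_weights_.append(alpha)
            w = w * np.exp(alpha * miss)
            w /= w.sum()
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        total = np.zeros((X.shape[0], self.classes_.size))
        for stump, alpha in zip(self.estimators_, self.estimator_weights_):
            p = stump.predict_proba(X)
            aligned = np.zeros_like(total)
            for j, c in enumerate(stump.classes_):
                aligned[:, np.searchsorted(self.classes_, c)] = p[:, j]
            total += alpha * aligned
        total /= sum(self.estimator_weights_)
        return total

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
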