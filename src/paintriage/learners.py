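"""Baseline learner registry and cross-validated evaluation.

Ten imbalance-aware baseline classifiers behind one ``fit`` /
``predict_proba`` contract: four resampling ensembles, class-weighted
random forest and logistic variants, one-class SVM (novelty detection on
the negative class) and a class-weighted SVC. Evaluation is pooled
out-of-fold: every patient is scored by the model not trained on their
fold, and one confusion matrix / AUC is computed over the pooled scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, OneClassSVM

from .ensembles import (
    BalancedBaggingClassifier,
    BalancedRandomForestClassifier,
    EasyEnsembleClassifier,
    RUSBoostClassifier,
)

logger = logging.getLogger("paintriage")

__all__ = [
    "REGISTRY",
    "BaseLearnerSpec",
    "FoldAssignment",
    "MetricsSummary",
    "RegistryError",
    "DegenerateStratificationWarning",
    "make_learner",
    "stratified_folds",
    "binary_metrics",
    "oof_predict",
    "cv_evaluate",
    "run_baseline_suite",
    "BaselineSuiteResult",
]


class RegistryError(KeyError):
    """Unknown learner name."""


class DegenerateStratificationWarning(UserWarning):
    """Fewer positives than folds: stratification cannot place one per fold."""


@dataclass(frozen=True)
class BaseLearnerSpec:
    """A named baseline learner with hyperparameters and a seed.

    ``name`` must belong to the closed registry; the seed propagates to
    every stochastic component of the learner.
    """

    name: str
    hyperparams: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def with_seed(self, seed: int) -> "BaseLearnerSpec":
        return BaseLearnerSpec(self.name, dict(self.hyperparams), seed)


class OneClassScorer:
    """One-class SVM fitted on the negative (majority) class only.

    Produces probability-like scores by min-max rescaling the negated
    decision function of each scored batch to [0, 1]: the further outside
    the learned negative-class envelope, the higher the positive score.
    """

    def __init__(self, seed: int = 0, **hyperparams):
        self.model = Pipeline(
            [("scale", StandardScaler()), ("ocsvm", OneClassSVM(**hyperparams))]
        )
        self.classes_ = np.array([0, 1])

    def fit(self, X, y):
        y = np.asarray(y)
        neg = np.asarray(X, dtype=float)[y == 0]
        if neg.shape[0] == 0:
            raise ValueError("one_class_svm requires at least one negative case")
        self.model.fit(neg)
        return self

    def predict_proba(self, X):
        score = -self.model.decision_function(np.asarray(X, dtype=float))
        lo, hi = score.min(), score.max()
        p1 = np.full_like(score, 0.5) if hi == lo else (score - lo) / (hi - lo)
        return np.column_stack([1.0 - p1, p1])


def _scaled(estimator) -> Pipeline:
    return Pipeline([("scale", StandardScaler()), ("clf", estimator)])


def _logistic(seed, penalty="l2", **hp):
    # l1_ratio is the post-1.8 sklearn spelling of the penalty choice
    kwargs = dict(l1_ratio=1.0, solver="liblinear") if penalty == "l1" else {}
    return _scaled(
        LogisticRegression(
            class_weight="balanced",
            max_iter=5000,
            random_state=seed,
            **kwargs,
            **hp,
        )
    )


REGISTRY: dict[str, Callable[..., object]] = {
    "easy_ensemble": lambda seed, **hp: EasyEnsembleClassifier(random_state=seed, **hp),
    "balanced_bagging": lambda seed, **hp: BalancedBaggingClassifier(
        random_state=seed, **hp
    ),
    "rus_boost": lambda seed, **hp: RUSBoostClassifier(random_state=seed, **hp),
    "random_forest": lambda seed, **hp: RandomForestClassifier(
        class_weight="balanced", random_state=seed, **hp
    ),
    "balanced_random_forest": lambda seed, **hp: BalancedRandomForestClassifier(
        random_state=seed, **hp
    ),
    "logistic": lambda seed, **hp: _logistic(seed, **hp),
    "logistic_l1": lambda seed, **hp: _logistic(seed, penalty="l1", **hp),
    "logistic_l2": lambda seed, **hp: _logistic(seed, penalty="l2", **hp),
    "one_class_svm": lambda seed, **hp: OneClassScorer(seed=seed, **hp),
    "svc": lambda seed, **hp: _scaled(
        # Platt-calibrated SVC: the probability surface sklearn's
        # probability=True used to provide, in its supported spelling
        CalibratedClassifierCV(
            SVC(class_weight="balanced", random_state=seed, **hp), ensemble=False
        )
    ),
}


def make_learner(spec: BaseLearnerSpec):
    """Instantiate a freshly seeded learner from the closed registry."""
    try:
        factory = REGISTRY[spec.name]
    except KeyError:
        raise RegistryError(
            f"unknown learner {spec.name!r}; valid names: {sorted(REGISTRY)}"
        ) from None
    return factory(spec.seed, **dict(spec.hyperparams))


# ---------------------------------------------------------------------------
# folds

@dataclass(frozen=True)
class FoldAssignment:
    """A stratified k-fold partition: per-patient fold index in [0, k)."""

    k: int
    fold_index: np.ndarray

    def test_mask(self, fold: int) -> np.ndarray:
        return self.fold_index == fold

    @property
    def n(self) -> int:
        return self.fold_index.size


def stratified_folds(y, k: int, seed: int = 0) -> FoldAssignment:
    """Stratified k-fold assignment; deterministic given ``seed``.

    Each fold's positive count differs from the ideal proportional share
    by at most one. With fewer positives than folds a
    :class:`DegenerateStratificationWarning` is raised.
    """
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > y.size:
        raise ValueError(f"k={k} exceeds the number of patients ({y.size})")
    if int(y.sum()) < k:
        warnings.warn(
            f"only {int(y.sum())} positives for {k} folds; some folds will "
            "hold no positive case",
            DegenerateStratificationWarning,
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_index = np.empty(y.size, dtype=int)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*least populated class.*")
        for f, (_, test_idx) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
            fold_index[test_idx] = f
    return FoldAssignment(k=k, fold_index=fold_index)


# ---------------------------------------------------------------------------
# metrics

@dataclass
class MetricsSummary:
    """Pooled out-of-fold classification metrics at one threshold.

    The tie rule is fixed: probability strictly greater than the threshold
    counts as a positive call; exactly equal counts negative. ``recall``
    equals ``tpr`` by construction. ``degenerate`` flags metrics that are
    undefined (no positives / no predicted positives) instead of silently
    reporting zero.
    """

    auc: float
    tpr: float
    tnr: float
    precision: float
    recall: float
    f1: float
    threshold: float
    fold_aucs: tuple[float, ...] | None = None
    degenerate: str | None = None


def mann_whitney_auc(y, probs) -> float:
    """AUC as the Mann–Whitney U statistic (rank form, ties averaged)."""
    y = np.asarray(y)
    probs = np.asarray(probs, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(probs)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def binary_metrics(y, probs, threshold: float = 0.5) -> MetricsSummary:
    """Confusion-matrix metrics plus AUC from pooled probabilities."""
    y = np.asarray(y)
    probs = np.asarray(probs, dtype=float)
    pred = probs > threshold  # strict: ties at the threshold are negative
    tp = int(np.sum(pred & (y == 1)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    degenerate = None
    if tp + fn == 0:
        degenerate = "no_positive_cases"
    elif tp + fp == 0:
        degenerate = "no_predicted_positives"
    tpr = tp / (tp + fn) if tp + fn else float("nan")
    tnr = tn / (tn + fp) if tn + fp else float("nan")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tpr if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return MetricsSummary(
        auc=mann_whitney_auc(y, probs),
        tpr=tpr,
        tnr=tnr,
        precision=precision,
        recall=recall,
        f1=f1,
        threshold=threshold,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# out-of-fold prediction

def oof_predict(
    spec: BaseLearnerSpec, X: np.ndarray, y, folds: FoldAssignment
) -> tuple[np.ndarray, np.ndarray, list[object]]:
    """Pooled out-of-fold probabilities.

    Fits one freshly seeded learner per fold on the training folds only and
    scores the held-out fold. Returns ``(probs, valid, fold_models)``;
    ``valid`` is False for patients in folds whose training split held no
    positive case (those folds are skipped and logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    probs = np.full(y.size, np.nan)
    valid = np.ones(y.size, dtype=bool)
    fold_models: list[object] = []
    for f in range(folds.k):
        test = folds.test_mask(f)
        train = ~test
        if int(y[train].sum()) == 0:
            warnings.warn(
                f"fold {f}: training split has no positive case; fold skipped",
                UserWarning,
                stacklevel=2,
            )
            logger.warning(
                "oof_predict[%s]: fold %d skipped (no positives in training)",
                spec.name,
                f,
            )
            valid[test] = False
            fold_models.append(None)
            continue
        learner = make_learner(spec.with_seed(spec.seed + 1000 * f))
        learner.fit(X[train], y[train])
        probs[test] = learner.predict_proba(X[test])[:, 1]
        fold_models.append(learner)
    return probs, valid, fold_models


def cv_evaluate(
    spec: BaseLearnerSpec,
    X,
    y,
    folds: FoldAssignment,
    threshold: float = 0.5,
):
    """Cross-validated evaluation with pooled out-of-fold scoring.

    Returns ``(MetricsSummary, StageProbabilities)``; metrics (including
    per-fold AUCs for downstream confidence intervals) are computed only on
    folds that could be fitted.
    """
    from .model import StageProbabilities  # local import to avoid a cycle

    X = np.asarray(X.values if hasattr(X, "values") else X, dtype=float)
    y = np.asarray(y)
    probs, valid, _ = oof_predict(spec, X, y, folds)
    metrics = binary_metrics(y[valid], probs[valid], threshold)
    fold_aucs = []
    for f in range(folds.k):
        m = folds.test_mask(f) & valid
        if m.any() and 0 < y[m].sum() < m.sum():
            fold_aucs.append(mann_whitney_auc(y[m], probs[m]))
    metrics.fold_aucs = tuple(fold_aucs)
    oof = StageProbabilities(
        stage_index=1, probs=probs, provenance="out_of_fold", valid=valid
    )
    return metrics, oof


# ---------------------------------------------------------------------------
# baseline suite

@dataclass
class BaselineSuiteResult:
    """Model × procedure metrics grid plus per-model cross-procedure ranges."""

    grid: pd.DataFrame
    ranges: pd.DataFrame
    manifest: dict

    def write(self, directory) -> None:
        from pathlib import Path
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.grid.to_csv(directory / "baseline_grid.csv", index=False)
        self.ranges.to_csv(directory / "baseline_ranges.csv", index=False)
        (directory / "baseline_manifest.json").write_text(
            json.dumps(self.manifest, indent=2)
        )


def run_baseline_suite(
    X,
    outcomes,
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
    models: list[str] | None = None,
) -> BaselineSuiteResult:
    """Evaluate every registry model on every procedure outcome.

    One fold assignment per procedure is shared across all models so that
    the grid is comparable cell to cell. Deterministic given ``seed``.
    """
    X = np.asarray(X.values if hasattr(X, "values") else X, dtype=float)
    labels = outcomes.labels if hasattr(outcomes, "labels") else dict(outcomes)
    model_names = models if models is not None else list(REGISTRY)
    rows = []
    for proc, y in labels.items():
        folds = stratified_folds(y, k=k, seed=seed)
        for name in model_names:
            spec = BaseLearnerSpec(name, seed=seed)
            metrics, _ = cv_evaluate(spec, X, y, folds, threshold)
            rows.append(
                {
                    "model": name,
                    "procedure": proc,
                    "auc": metrics.auc,
                    "tpr": metrics.tpr,
                    "tnr": metrics.tnr,
                }
            )
    grid = pd.DataFrame(rows)
    ranges = (
        grid.melt(
            id_vars=["model", "procedure"], var_name="metric", value_name="value"
        )
        .groupby(["model", "metric"], sort=False)["value"]
        .agg(["min", "max"])
        .reset_index()
    )
    manifest = {
        "k": k,
        "seed": seed,
        "threshold": threshold,
        "models": model_names,
        "procedures": list(labels),
    }
    return BaselineSuiteResult(grid=grid, ranges=ranges, manifest=manifest)
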