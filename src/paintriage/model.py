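"""Multistage (stacked) classification with elbow-method stage selection.

The core procedure: fit a base learner with stratified 10-fold cross
validation, append its pooled out-of-fold predicted probabilities to the
feature matrix as a new column, refit on the augmented matrix, and repeat.
Stage i therefore learns from the original features x_1..x_n plus the
probability vectors y_1..y_{i-1} of the earlier stages (cumulative mode;
``last_only`` appends only y_{i-1}). After M_max stages the elbow rule on
the TPR trajectory picks the stage i* where the slope change is maximal,
and the deployed model is the chain of full-data refits truncated at i*.

One fold assignment is fixed up front and reused at every stage, so a
patient's own probability at any stage is produced by models that never
trained on that patient's fold, and the trajectory is comparable stage to
stage.

The model/results split follows the statsmodels convention:

>>> model = MultistageTriage(X, y, base_spec=BaseLearnerSpec("easy_ensemble"))
>>> res = model.fit(seed=0)
>>> res.selected_stage, res.trace.p
>>> print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .cohort import FeatureMatrix
from .elbow import StageTrace
from .learners import (
    BaseLearnerSpec,
    FoldAssignment,
    MetricsSummary,
    binary_metrics,
    make_learner,
    mann_whitney_auc,
    oof_predict,
    stratified_folds,
)

__all__ = [
    "StageProbabilities",
    "StageResult",
    "SchemaError",
    "augment",
    "run_stage",
    "fit_multistage",
    "MultistageTriage",
    "MultistageResults",
]


class SchemaError(ValueError):
    """Prediction input does not match the training feature schema."""


@dataclass
class StageProbabilities:
    """Per-patient predicted probabilities produced at one stage.

    ``provenance`` records whether the vector is pooled out-of-fold
    (training-time, leakage-safe) or from a full-data model chain
    (inference-time). ``valid`` is False for patients in skipped folds.
    """

    stage_index: int
    probs: np.ndarray
    provenance: str = "out_of_fold"
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.probs.size, dtype=bool)
        if self.provenance not in ("out_of_fold", "full_model"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return self.probs.size


@dataclass
class StageResult:
    """One fitted stage: pooled-OOF metrics, OOF vector, full-data learner."""

    stage_index: int
    metrics: MetricsSummary
    oof: StageProbabilities
    fitted_learner: object
    feature_names: list[str] = field(default_factory=list)


def augment(
    X: FeatureMatrix,
    history: list[StageProbabilities],
    mode: str = "cumulative",
) -> FeatureMatrix:
    """Append earlier-stage probability vectors as ``stage_prob_<j>`` columns.

    Cumulative mode appends every vector in stage order; ``last_only``
    appends only the most recent. Original columns are unchanged and keep
    their order. With an empty history the matrix is returned as is.
    """
    if mode not in ("cumulative", "last_only"):
        raise ValueError(f"unknown augmentation mode {mode!r}")
    if not history:
        return X
    use = history if mode == "cumulative" else history[-1:]
    cols, names, kinds = [X.values], list(X.feature_names), list(X.feature_kind)
    for sp in use:
        if len(sp) != X.n_patients:
            raise ValueError(
                f"stage {sp.stage_index} probabilities have {len(sp)} entries, "
                f"expected {X.n_patients}"
            )
        cols.append(sp.probs[:, None])
        names.append(f"stage_prob_{sp.stage_index}")
        kinds.append("stage_prob")
    return FeatureMatrix(np.hstack(cols), names, kinds)


def run_stage(
    base_spec: BaseLearnerSpec,
    X_aug: FeatureMatrix,
    y,
    folds: FoldAssignment,
    threshold: float = 0.5,
    stage_index: int = 1,
) -> StageResult:
    """Fit one stage: per-fold models for pooled OOF, one full-data refit.

    Metrics are computed from the pooled out-of-fold probabilities at the
    threshold; the full-data learner is stored for the inference chain.
    """
    y = np.asarray(y)
    probs, valid, _ = oof_predict(base_spec, X_aug.values, y, folds)
    metrics = binary_metrics(y[valid], probs[valid], threshold)
    fold_aucs = []
    for f in range(folds.k):
        m = folds.test_mask(f) & valid
        if m.any() and 0 < y[m].sum() < m.sum():
            fold_aucs.append(mann_whitney_auc(y[m], probs[m]))
    metrics.fold_aucs = tuple(fold_aucs)
    full = make_learner(base_spec)
    full.fit(X_aug.values, y)
    oof = StageProbabilities(
        stage_index=stage_index, probs=probs, provenance="out_of_fold", valid=valid
    )
    return StageResult(
        stage_index=stage_index,
        metrics=metrics,
        oof=oof,
        fitted_learner=full,
        feature_names=list(X_aug.feature_names),
    )


class MultistageTriage:
    """Multistage stacked classifier for one procedure outcome.

    Parameters
    ----------
    X : FeatureMatrix or DataFrame or ndarray
        Referral feature matrix.
    y : array-like of {0, 1}
        Procedure outcome labels.
    base_spec : BaseLearnerSpec
        The base learner refitted at every stage (default easy_ensemble,
        the imbalance-aware ensemble the framework is built around).
    k : int
        Cross-validation folds per stage (default 10).
    m_max : int
        Stages to train before elbow selection; at least 3 (the slope
        change needs an interior stage). Default 4.
    threshold : float
        Probability cut-off for TPR/TNR (default 0.5).
    mode : {"cumulative", "last_only"}
        Whether stage i receives all earlier probability vectors or only
        the latest.
    """

    def __init__(
        self,
        X,
        y,
        base_spec: BaseLearnerSpec | None = None,
        k: int = 10,
        m_max: int = 4,
        threshold: float = 0.5,
        mode: str = "cumulative",
        procedure: str | None = None,
    ):
        if m_max < 3:
            raise ValueError(
                "m_max must be at least 3: the slope-change statistic needs "
                "a trajectory with an interior stage"
            )
        if isinstance(X, FeatureMatrix):
            self.X = X
        elif isinstance(X, pd.DataFrame):
            self.X = FeatureMatrix(
                X.to_numpy(dtype=float),
                list(X.columns),
                ["structured"] * X.shape[1],
            )
        else:
            arr = np.asarray(X, dtype=float)
            self.X = FeatureMatrix(
                arr,
                [f"x_{j}" for j in range(arr.shape[1])],
                ["structured"] * arr.shape[1],
            )
        self.y = np.asarray(y, dtype=int)
        if self.y.size != self.X.n_patients:
            raise ValueError("X and y have different numbers of patients")
        self.base_spec = base_spec or BaseLearnerSpec("easy_ensemble")
        self.k = k
        self.m_max = m_max
        self.threshold = threshold
        self.mode = mode
        self.procedure = procedure

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, outcome: str, feature_cols=None, **kwargs
    ) -> "MultistageTriage":
        """Build from a cohort frame with a ``label_<outcome>`` column."""
        label_col = outcome if outcome in df.columns else f"label_{outcome}"
        if label_col not in df.columns:
            raise SchemaError(f"outcome column {outcome!r} not found")
        if feature_cols is None:
            feature_cols = [c for c in df.columns if not c.startswith("label_")]
        kinds = [
            "nlp_flag" if c.startswith("nlp_") else "structured" for c in feature_cols
        ]
        fm = FeatureMatrix(df[feature_cols].to_numpy(dtype=float), list(feature_cols), kinds)
        return cls(fm, df[label_col].to_numpy(), procedure=outcome.removeprefix("label_"), **kwargs)

    def fit(self, seed: int = 0) -> "MultistageResults":
        """Train all stages, select i* by the elbow rule, return results."""
        folds = stratified_folds(self.y, k=self.k, seed=seed)
        spec = self.base_spec.with_seed(seed)
        history: list[StageProbabilities] = []
        stage_results: list[StageResult] = []
        for i in range(1, self.m_max + 1):
            X_aug = augment(self.X, history, self.mode)
            res = run_stage(
                spec, X_aug, self.y, folds, self.threshold, stage_index=i
            )
            stage_results.append(res)
            history.append(res.oof)
        trace = StageTrace.from_trajectory(
            p=[r.metrics.tpr for r in stage_results],
            tnr=[r.metrics.tnr for r in stage_results],
            auc=[r.metrics.auc for r in stage_results],
            fold_aucs=[r.metrics.fold_aucs for r in stage_results],
        )
        return MultistageResults(
            model=self,
            seed=seed,
            folds=folds,
            stage_results=stage_results,
            trace=trace,
            selected_stage=trace.selected,
        )


def fit_multistage(
    base_spec: BaseLearnerSpec,
    X,
    y,
    k: int = 10,
    seed: int = 0,
    m_max: int = 4,
    threshold: float = 0.5,
    mode: str = "cumulative",
) -> tuple["MultistageResults", StageTrace]:
    """Functional wrapper: fit a :class:`MultistageTriage` end to end."""
    model = MultistageTriage(
        X, y, base_spec=base_spec, k=k, m_max=m_max, threshold=threshold, mode=mode
    )
    res = model.fit(seed=seed)
    return res, res.trace


class MultistageResults:
    """Fitted multistage model: stage chain, trajectory, selected stage.

    The deployable chain is the full-data refits of stages 1..i*; the
    reported metrics always come from pooled out-of-fold predictions.
    """

    def __init__(self, model, seed, folds, stage_results, trace, selected_stage):
        self.model = model
        self.seed = seed
        self.folds = folds
        self.stage_results = stage_results  # all m_max stages (immutable record)
        self.trace = trace
        self.selected_stage = selected_stage
        # the deployed chain truncates at the selected stage
        self.stages = [r.fitted_learner for r in stage_results[:selected_stage]]
        self.schemas = [r.feature_names for r in stage_results[:selected_stage]]

    # -- convenience -----------------------------------------------------
    @property
    def procedure(self) -> str | None:
        return self.model.procedure

    @property
    def threshold(self) -> float:
        return self.model.threshold

    @property
    def final_result(self) -> StageResult:
        return self.stage_results[self.selected_stage - 1]

    @property
    def final_oof(self) -> StageProbabilities:
        return self.final_result.oof

    def oof_history(self, up_to: int | None = None) -> list[StageProbabilities]:
        up_to = self.selected_stage if up_to is None else up_to
        return [r.oof for r in self.stage_results[:up_to]]

    # -- inference -------------------------------------------------------
    def _check_schema(self, X_new) -> np.ndarray:
        base_schema = self.schemas[0][: self.model.X.n_features]
        if isinstance(X_new, FeatureMatrix):
            names, arr = list(X_new.feature_names), X_new.values
        elif isinstance(X_new, pd.DataFrame):
            names, arr = list(X_new.columns), X_new.to_numpy(dtype=float)
        else:
            arr = np.asarray(X_new, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != len(base_schema):
                raise SchemaError(
                    f"expected {len(base_schema)} feature columns, got "
                    f"{arr.shape[1] if arr.ndim == 2 else 'non-2D input'}"
                )
            return arr
        missing = [c for c in base_schema if c not in names]
        extra = [c for c in names if c not in base_schema]
        if missing or extra:
            raise SchemaError(
                f"feature schema mismatch; missing columns: {missing}, "
                f"unexpected columns: {extra}"
            )
        order = [names.index(c) for c in base_schema]
        return arr[:, order]

    def predict(self, X_new) -> StageProbabilities:
        """Score new referrals through the truncated full-model chain."""
        arr = self._check_schema(X_new)
        n = arr.shape[0]
        fm = FeatureMatrix(
            arr,
            self.schemas[0][: self.model.X.n_features],
            ["structured"] * arr.shape[1],
        )
        history: list[StageProbabilities] = []
        probs = None
        for i, learner in enumerate(self.stages, start=1):
            X_aug = augment(fm, history, self.model.mode)
            probs = learner.predict_proba(X_aug.values)[:, 1]
            history.append(
                StageProbabilities(
                    stage_index=i, probs=probs, provenance="full_model"
                )
            )
        return StageProbabilities(
            stage_index=self.selected_stage, probs=probs, provenance="full_model"
        )

    # -- evaluation ------------------------------------------------------
    def final_metrics(self, level: float = 0.95):
        """Pooled final-stage metrics plus the fold-AUC t-interval summary."""
        from .evaluation import final_metrics

        r = self.final_result
        return final_metrics(
            r.oof, self.model.y, self.threshold, r.metrics.fold_aucs, level=level
        )

    def accounting(self, up_to: int | None = None):
        """Per-stage capture/loss accounting of positives and negatives."""
        from .evaluation import stage_accounting

        return stage_accounting(self.oof_history(up_to), self.model.y, self.threshold)

    def calibration_table(self, n_bins: int = 10):
        from .evaluation import calibration_bins

        oof = self.final_oof
        return calibration_bins(
            oof.probs[oof.valid], self.model.y[oof.valid], n_bins=n_bins
        )

    def probability_histogram(self, bin_width: float = 0.1, up_to: int | None = None):
        from .evaluation import probability_histogram

        return probability_histogram(
            self.oof_history(up_to if up_to is not None else len(self.stage_results)),
            self.model.y,
            bin_width=bin_width,
        )

    def feature_importance(self, top_k: int = 10) -> pd.DataFrame:
        """Mean impurity importance across the final stage's ensemble members."""
        imp = _impurity_importance(self.stages[-1])
        if imp is None:
            raise ValueError(
                f"learner {self.model.base_spec.name!r} exposes no impurity importance"
            )
        names = self.schemas[-1]
        df = pd.DataFrame({"feature": names, "importance": imp})
        return df.sort_values("importance", ascending=False).head(top_k).reset_index(
            drop=True
        )

    def summary(self) -> str:
        """Human-readable fit report (stage trajectory + final metrics)."""
        m, ci = self.final_metrics()
        lines = [
            "Multistage stacked classifier",
            "=" * 64,
            f"procedure: {self.procedure or '-'}   base learner: {self.model.base_spec.name}",
            f"patients: {self.model.X.n_patients}   positives: {int(self.model.y.sum())}"
            f"   features: {self.model.X.n_features}",
            f"folds: {self.folds.k}   stages trained: {len(self.stage_results)}"
            f"   selected stage i*: {self.selected_stage}   threshold: {self.threshold}",
            "-" * 64,
            self.trace.to_frame().to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            ),
            "-" * 64,
            f"final stage {self.selected_stage} (pooled out-of-fold):",
            f"  precision {m.precision:.4f}   recall {m.recall:.4f}   F1 {m.f1:.4f}",
            f"  AUC {ci.mean:.4f} +/- {ci.sd:.4f}  "
            f"[{ci.ci_low:.4f}, {ci.ci_high:.4f}] ({int(ci.level*100)}% CI, "
            f"{ci.k} fold AUCs)",
        ]
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        """Persist the truncated chain: one learner per stage + manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, learner in enumerate(self.stages, start=1):
            joblib.dump(learner, directory / f"stage_{i}.joblib")
        manifest = {
            "procedure": self.procedure,
            "base_spec": {
                "name": self.model.base_spec.name,
                "hyperparams": dict(self.model.base_spec.hyperparams),
                "seed": self.model.base_spec.seed,
            },
            "k": self.folds.k,
            "m_max": self.model.m_max,
            "seed": self.seed,
            "threshold": self.threshold,
            "mode": self.model.mode,
            "selected_stage": self.selected_stage,
            "schemas": self.schemas,
            "fold_aucs": {
                str(r.stage_index): list(r.metrics.fold_aucs or [])
                for r in self.stage_results
            },
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        self.trace.to_frame().to_csv(directory / "stage_trace.csv", index=False)
        oof = pd.DataFrame(
            {f"stage_{r.stage_index}": r.oof.probs for r in self.stage_results}
        )
        oof["label"] = self.model.y
        oof.to_csv(directory / "oof_probabilities.csv", index=False)
        return directory

    @staticmethod
    def load_chain(directory: str | Path) -> "LoadedChain":
        return LoadedChain.load(directory)


class LoadedChain:
    """A persisted multistage chain reloaded for inference only."""

    def __init__(self, stages, manifest):
        self.stages = stages
        self.manifest = manifest
        self.selected_stage = manifest["selected_stage"]
        self.mode = manifest["mode"]
        self.schemas = manifest["schemas"]

    @classmethod
    def load(cls, directory: str | Path) -> "LoadedChain":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        stages = [
            joblib.load(directory / f"stage_{i}.joblib")
            for i in range(1, manifest["selected_stage"] + 1)
        ]
        return cls(stages, manifest)

    def predict(self, X_new) -> StageProbabilities:
        base_schema = self.schemas[0]
        if isinstance(X_new, pd.DataFrame):
            missing = [c for c in base_schema if c not in X_new.columns]
            extra = [
                c
                for c in X_new.columns
                if c not in base_schema and not c.startswith("label_")
            ]
            if missing or extra:
                raise SchemaError(
                    f"feature schema mismatch; missing columns: {missing}, "
                    f"unexpected columns: {extra}"
                )
            arr = X_new[base_schema].to_numpy(dtype=float)
        else:
            arr = np.asarray(X_new, dtype=float)
            if arr.shape[1] != len(base_schema):
                raise SchemaError(
                    f"expected {len(base_schema)} feature columns, got {arr.shape[1]}"
                )
        fm = FeatureMatrix(arr, base_schema, ["structured"] * len(base_schema))
        history: list[StageProbabilities] = []
        probs = None
        for i, learner in enumerate(self.stages, start=1):
            X_aug = augment(fm, history, self.mode)
            probs = learner.predict_proba(X_aug.values)[:, 1]
            history.append(
                StageProbabilities(stage_index=i, probs=probs, provenance="full_model")
            )
        return StageProbabilities(
            stage_index=self.selected_stage, probs=probs, provenance="full_model"
        )


def _impurity_importance(learner) -> np.ndarray | None:
    """Mean impurity importance across ensemble members, where available."""
    if hasattr(learner, "feature_importances_"):
        return np.asarray(learner.feature_importances_)
    if hasattr(learner, "estimators_"):
        parts = [_impurity_importance(m) for m in learner.estimators_]
        parts = [p for p in parts if p is not None]
        if parts:
            return np.mean(parts, axis=0)
    if hasattr(learner, "named_steps"):  # scaled linear models
        clf = learner.named_steps.get("clf")
        if clf is not None and hasattr(clf, "coef_"):
            return np.abs(np.asarray(clf.coef_)).ravel()
    return None
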