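"""Final-stage evaluation: CI convention, stage accounting, calibration.

The AUC confidence interval follows the fold convention: the k
out-of-fold AUCs are summarised as mean ± sample SD, and the interval is
the Student-t interval mean ± t_{(1+level)/2, k-1} · sd/√k. Stage
accounting reduces per-patient correctness trajectories across stages to
the counts of cases captured at stage 1, newly captured, lost, and never
captured, separately for positives and negatives. Calibration uses
fixed-width probability bins, which under low prevalence leaves upper
bins sparsely occupied — exactly the regime these tables are meant to
expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .learners import MetricsSummary, binary_metrics

__all__ = [
    "FoldAUCSummary",
    "StageAccounting",
    "ClassAccounting",
    "CalibrationTable",
    "DegenerateMetricsError",
    "t_interval",
    "summarize_fold_aucs",
    "final_metrics",
    "stage_accounting",
    "calibration_bins",
    "probability_histogram",
]


class DegenerateMetricsError(ValueError):
    """Metrics undefined (e.g. no positive cases in the labels)."""


def t_interval(
    mean: float, sd: float, k: int, level: float = 0.95
) -> tuple[float, float]:
    """Student-t confidence interval for a mean of k fold-level values.

    Returns ``mean ± t_{(1+level)/2, k-1} · sd/√k``. ``sd`` is the sample
    standard deviation (k−1 denominator) of the fold values.
    """
    if k < 2:
        raise ValueError("k must be at least 2 for a t interval")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    half = stats.t.ppf((1.0 + level) / 2.0, df=k - 1) * sd / np.sqrt(k)
    return (mean - half, mean + half)


@dataclass
class FoldAUCSummary:
    """Mean ± SD of per-fold AUCs with the Student-t confidence interval."""

    fold_aucs: tuple[float, ...]
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    @property
    def k(self) -> int:
        return len(self.fold_aucs)


def summarize_fold_aucs(fold_aucs, level: float = 0.95) -> FoldAUCSummary:
    fold_aucs = tuple(float(a) for a in fold_aucs)
    if len(fold_aucs) < 2:
        raise ValueError("need at least 2 fold AUCs to summarise")
    mean = float(np.mean(fold_aucs))
    sd = float(np.std(fold_aucs, ddof=1))
    lo, hi = t_interval(mean, sd, len(fold_aucs), level)
    return FoldAUCSummary(fold_aucs, mean, sd, lo, hi, level)


def _probs_of(x) -> np.ndarray:
    return np.asarray(getattr(x, "probs", x), dtype=float)


def final_metrics(
    oof, y, threshold: float = 0.5, fold_aucs=None, level: float = 0.95
) -> tuple[MetricsSummary, FoldAUCSummary | None]:
    """Pooled final-stage metrics plus the fold-AUC summary.

    Precision/recall/F1 come from one confusion matrix over the pooled
    out-of-fold predictions at the threshold; F1 is 0 when precision and
    recall are both 0. Raises :class:`DegenerateMetricsError` when the
    labels contain no positive case.
    """
    y = np.asarray(y)
    probs = _probs_of(oof)
    valid = getattr(oof, "valid", None)
    if valid is not None:
        probs, y = probs[valid], y[valid]
    if int(y.sum()) == 0:
        raise DegenerateMetricsError(
            "labels contain no positive case; precision/recall are undefined"
        )
    metrics = binary_metrics(y, probs, threshold)
    summary = None
    if fold_aucs is None:
        fold_aucs = getattr(oof, "fold_aucs", None)
    if fold_aucs:
        summary = summarize_fold_aucs(fold_aucs, level)
        metrics.fold_aucs = tuple(float(a) for a in fold_aucs)
    return metrics, summary


# ---------------------------------------------------------------------------
# stage accounting

@dataclass
class ClassAccounting:
    """Stage-transition counts for one class (positives or negatives).

    ``newly_captured[j]`` counts cases wrong at every stage before j and
    correct at stage j; ``lost[j]`` counts cases correct at some earlier
    stage but wrong at stage j. ``never_captured`` cases are wrong at all
    stages. Stage keys run 2..M.
    """

    total: int
    captured_stage1: int
    newly_captured: dict[int, int]
    lost: dict[int, int]
    never_captured: int
    final_correct: int
    correct_by_stage: tuple[int, ...]

    @property
    def final_rate(self) -> float:
        return self.final_correct / self.total if self.total else float("nan")


@dataclass
class StageAccounting:
    """Per-class stage accounting plus the per-patient correctness lattice."""

    positive: ClassAccounting
    negative: ClassAccounting
    n_stages: int
    correct: np.ndarray = field(repr=False)  # patients × stages boolean
    y: np.ndarray = field(repr=False)

    @property
    def tpr_final(self) -> float:
        return self.positive.final_rate

    @property
    def tnr_final(self) -> float:
        return self.negative.final_rate

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls_name, acc in (("positive", self.positive), ("negative", self.negative)):
            rows.append(
                {
                    "class": cls_name,
                    "total": acc.total,
                    "captured_stage1": acc.captured_stage1,
                    **{f"newly_captured_{j}": v for j, v in acc.newly_captured.items()},
                    **{f"lost_{j}": v for j, v in acc.lost.items()},
                    "never_captured": acc.never_captured,
                    "final_correct": acc.final_correct,
                    "final_rate": acc.final_rate,
                }
            )
        return pd.DataFrame(rows)


def _class_accounting(correct: np.ndarray) -> ClassAccounting:
    n, m = correct.shape
    newly: dict[int, int] = {}
    lost: dict[int, int] = {}
    for j in range(1, m):  # stages 2..m
        wrong_before = ~correct[:, :j].any(axis=1)
        newly[j + 1] = int(np.sum(wrong_before & correct[:, j]))
        correct_before = correct[:, :j].any(axis=1)
        lost[j + 1] = int(np.sum(correct_before & ~correct[:, j]))
    return ClassAccounting(
        total=n,
        captured_stage1=int(correct[:, 0].sum()) if m else 0,
        newly_captured=newly,
        lost=lost,
        never_captured=int(np.sum(~correct.any(axis=1))),
        final_correct=int(correct[:, -1].sum()),
        correct_by_stage=tuple(int(c) for c in correct.sum(axis=0)),
    )


def stage_accounting(stage_oof, y, threshold: float = 0.5) -> StageAccounting:
    """Reduce per-stage predictions to capture/loss counts per class.

    ``stage_oof`` is an ordered list of per-stage probability vectors (or
    :class:`~paintriage.model.StageProbabilities`). A prediction is correct
    when the thresholded call (strictly greater than the threshold →
    positive) matches the label.
    """
    if not stage_oof:
        raise ValueError("need at least one stage of predictions")
    y = np.asarray(y)
    preds = np.column_stack([_probs_of(sp) > threshold for sp in stage_oof])
    if preds.shape[0] != y.size:
        raise ValueError("stage predictions and labels are not conformable")
    correct = preds == y[:, None]
    return StageAccounting(
        positive=_class_accounting(correct[y == 1]),
        negative=_class_accounting(correct[y == 0]),
        n_stages=preds.shape[1],
        correct=correct,
        y=y,
    )


# ---------------------------------------------------------------------------
# calibration / probability distribution

@dataclass
class CalibrationTable:
    """Fixed-width calibration bins: count, mean predicted, observed fraction."""

    table: pd.DataFrame
    n_bins: int
    prevalence: float

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def calibration_bins(probs, y, n_bins: int = 10) -> CalibrationTable:
    """Bin probabilities into ``n_bins`` equal-width bins on [0, 1].

    Bins are half-open [lo, hi) with the last bin closed at 1. Empty bins
    carry ``empty=True`` and NaN summaries. The count-weighted mean of the
    observed fractions equals the overall prevalence.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y)
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.minimum(np.digitize(probs, edges[1:-1], right=False), n_bins - 1)
    rows = []
    for b in range(n_bins):
        in_bin = idx == b
        count = int(in_bin.sum())
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "count": count,
                "mean_predicted": float(probs[in_bin].mean()) if count else np.nan,
                "observed_fraction": float(y[in_bin].mean()) if count else np.nan,
                "empty": count == 0,
            }
        )
    table = pd.DataFrame(rows)
    return CalibrationTable(
        table=table, n_bins=n_bins, prevalence=float(np.mean(y)) if y.size else np.nan
    )


def probability_histogram(stage_oof, y, bin_width: float = 0.1) -> pd.DataFrame:
    """Per-stage histogram of predicted probabilities with positive overlay.

    Returns one row per (stage, bin) with counts over all patients and
    over positive cases only — the export behind probability-distribution
    figures showing how the positive mass migrates across stages.
    """
    if not stage_oof:
        raise ValueError("need at least one stage of predictions")
    if not 0 < bin_width <= 1:
        raise ValueError("bin_width must lie in (0, 1]")
    y = np.asarray(y)
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    rows = []
    for pos, sp in enumerate(stage_oof, start=1):
        probs = _probs_of(sp)
        if probs.size != y.size:
            raise ValueError("stage predictions and labels are not conformable")
        idx = np.minimum(np.digitize(probs, edges[1:-1], right=False), n_bins - 1)
        stage = getattr(sp, "stage_index", pos)
        for b in range(n_bins):
            in_bin = idx == b
            rows.append(
                {
                    "stage": stage,
                    "bin_lo": edges[b],
                    "bin_hi": edges[b + 1],
                    "count_all": int(in_bin.sum()),
                    "count_positive": int((in_bin & (y == 1)).sum()),
                }
            )
    return pd.DataFrame(rows)
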