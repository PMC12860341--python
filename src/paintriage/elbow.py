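"""Elbow-method stage selection on a TPR trajectory.

Given the true-positive-rate trajectory p_1..p_M across stacking stages,
the slope-change statistic at interior stage i is

    s_i = |(p_i - p_{i-1}) - (p_{i+1} - p_i)|,

the absolute change in improvement rate entering versus leaving stage i —
a discrete second difference. The selected stage i* maximises s_i; ties
break toward the smallest stage (parsimony: fewer stages, less overfitting
risk). s is well-defined for interior stages 2..M-1 only, so a trajectory
needs at least three stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrajectoryTooShortError", "slope_changes", "select_stage", "StageTrace"]


class TrajectoryTooShortError(ValueError):
    """The slope-change statistic needs a trajectory of at least 3 stages."""


def slope_changes(p) -> np.ndarray:
    """Slope-change values s_2..s_{M-1} of a trajectory p_1..p_M.

    Equals ``|p_{i+1} - 2 p_i + p_{i-1}|``; scale-equivariant and
    invariant to adding a constant to every p.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 3:
        raise TrajectoryTooShortError(
            f"need at least 3 stages, got trajectory of length {p.size}"
        )
    return np.abs((p[1:-1] - p[:-2]) - (p[2:] - p[1:-1]))


def select_stage(s) -> int:
    """Stage index i* (2-based) of the maximal slope change.

    ``s[0]`` corresponds to stage 2. Ties break toward the smallest stage.
    """
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("empty slope-change sequence")
    return int(np.argmax(s)) + 2  # np.argmax returns the first maximum


@dataclass
class StageTrace:
    """TPR trajectory, slope changes and the selected stage.

    ``tnr``, ``auc`` and ``fold_aucs`` are auxiliary reporting
    trajectories; selection uses the TPR only.
    """

    p: np.ndarray
    s: np.ndarray
    selected: int
    tnr: np.ndarray | None = None
    auc: np.ndarray | None = None
    fold_aucs: list[tuple[float, ...]] | None = field(default=None, repr=False)

    @classmethod
    def from_trajectory(cls, p, tnr=None, auc=None, fold_aucs=None) -> "StageTrace":
        s = slope_changes(p)
        return cls(
            p=np.asarray(p, dtype=float),
            s=s,
            selected=select_stage(s),
            tnr=None if tnr is None else np.asarray(tnr, dtype=float),
            auc=None if auc is None else np.asarray(auc, dtype=float),
            fold_aucs=fold_aucs,
        )

    @property
    def n_stages(self) -> int:
        return self.p.size

    def to_frame(self) -> pd.DataFrame:
        """Per-stage table (stage, tpr, tnr, auc, slope_change, selected)."""
        m = self.n_stages
        s_full = np.full(m, np.nan)
        s_full[1:-1] = self.s
        df = pd.DataFrame({"stage": np.arange(1, m + 1), "tpr": self.p})
        if self.tnr is not None:
            df["tnr"] = self.tnr
        if self.auc is not None:
            df["auc"] = self.auc
        df["slope_change"] = s_full
        df["selected"] = df["stage"] == self.selected
        return df
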