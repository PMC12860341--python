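"""Referral triage decision rule.

A referral scored against all procedure models yields one probability per
procedure. The procedure with the highest probability is scheduled only
when its lead over the runner-up strictly exceeds the review margin;
otherwise the case is flagged for manual review by an advanced practice
provider. The margin is a mandatory, logged configuration value — "very
close" is a clinical judgement the deploying service must own.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["TriageDecision", "decide", "triage_table", "write_decisions"]


@dataclass(frozen=True)
class TriageDecision:
    """Outcome of the argmax-with-review-margin rule for one referral."""

    prob_map: dict[str, float]
    outcome: str  # "scheduled" | "manual_review"
    procedure: str | None  # set when scheduled
    margin: float
    top_two: tuple[str, ...]
    patient_id: int | str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def decide(
    prob_map: dict[str, float], margin: float = 0.10, patient_id=None
) -> TriageDecision:
    """Apply the argmax-with-review-margin rule to one probability map.

    Schedules the top procedure when its probability exceeds the
    runner-up's by strictly more than ``margin``; a single-procedure map
    is always scheduled; exact top ties never exceed a non-negative margin
    and go to manual review.
    """
    if not prob_map:
        raise ValueError("prob_map must name at least one procedure")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    for proc, p in prob_map.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for {proc!r} outside [0, 1]: {p}")
    ranked = sorted(prob_map, key=lambda proc: (-prob_map[proc], proc))
    top_two = tuple(ranked[:2])
    if len(ranked) == 1:
        return TriageDecision(
            dict(prob_map), "scheduled", ranked[0], margin, top_two, patient_id
        )
    lead = prob_map[ranked[0]] - prob_map[ranked[1]]
    if lead > margin:
        return TriageDecision(
            dict(prob_map), "scheduled", ranked[0], margin, top_two, patient_id
        )
    return TriageDecision(dict(prob_map), "manual_review", None, margin, top_two, patient_id)


def triage_table(prob_frame: pd.DataFrame, margin: float = 0.10) -> list[TriageDecision]:
    """Apply :func:`decide` row-wise to a patients × procedures frame."""
    return [
        decide(row.to_dict(), margin, patient_id=idx)
        for idx, row in prob_frame.iterrows()
    ]


def write_decisions(decisions: list[TriageDecision], path: str | Path) -> Path:
    """Write decisions as CSV plus JSON-lines (one record per patient)."""
    path = Path(path)
    rows = []
    for d in decisions:
        row = {
            "patient_id": d.patient_id,
            "outcome": d.outcome,
            "procedure": d.procedure if d.procedure is not None else "",
            "margin": d.margin,
            "top_1": d.top_two[0],
            "top_2": d.top_two[1] if len(d.top_two) > 1 else "",
        }
        row.update({f"prob_{p}": v for p, v in d.prob_map.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    jsonl = path.with_suffix(".jsonl")
    with jsonl.open("w") as fh:
        for d in decisions:
            fh.write(json.dumps(d.to_dict()) + "\n")
    return path
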