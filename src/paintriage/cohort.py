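"""Synthetic referral-cohort generator.

Emulates the statistical shape of a pain-medicine referral cohort: a few
thousand patients, a couple of hundred structured features (binary history
flags and non-negative visit/medication counts), a few dozen binary
NLP-concept flags, and five heavily imbalanced binary procedure outcomes
(peripheral nerve stimulation, spinal cord stimulation, intrathecal pump,
basivertebral radiofrequency ablation, minimally invasive lumbar
decompression).

Each outcome is driven by a latent score: a sparse linear combination of
standardized features, plus a handful of pairwise feature interactions,
plus Gaussian noise. Labels are assigned by ranking the latent score and
thresholding at the configured positive count, so per-procedure positive
counts are exact and downstream tests are deterministic. The interaction
terms make a single-stage linear learner suboptimal, leaving headroom for
stage augmentation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PROCEDURES",
    "CohortConfig",
    "FeatureMatrix",
    "OutcomeLabels",
    "InvalidConfigError",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "save_config",
    "load_config",
]

#: The five procedure outcomes, in canonical order.
PROCEDURES = ("PNS", "SCS", "ITP", "BVRF", "MILD")

#: Per-procedure positive counts of the reference referral cohort (3,552 referrals).
DEFAULT_OUTCOME_SPEC = {"PNS": 46, "SCS": 126, "ITP": 36, "BVRF": 16, "MILD": 10}


class InvalidConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


def _default_outcome_spec() -> dict[str, int]:
    return dict(DEFAULT_OUTCOME_SPEC)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic referral cohort.

    Parameters
    ----------
    n_patients : int
        Number of referred patients (rows). Default 3552.
    n_structured : int
        Number of structured features (EHR history: demographics,
        diagnoses, medications, appointment counts, comorbidities).
    n_nlp : int
        Number of binary NLP-concept flags extracted from clinical notes.
    outcome_spec : mapping of str to int
        Exact positive count per procedure outcome.
    signal_sparsity : float
        Fraction of features with a nonzero linear effect per outcome.
    interaction_pairs : int
        Number of pairwise feature interactions in each latent score.
    noise_scale : float
        Standard deviation of the Gaussian latent noise.
    seed : int
        Seed of the generator; same config and seed give bit-identical
        cohorts.
    """

    n_patients: int = 3552
    n_structured: int = 192
    n_nlp: int = 39
    outcome_spec: Mapping[str, int] = field(default_factory=_default_outcome_spec)
    signal_sparsity: float = 0.10
    interaction_pairs: int = 5
    noise_scale: float = 1.0
    seed: int = 0

    @property
    def n_features(self) -> int:
        return self.n_structured + self.n_nlp

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise InvalidConfigError("n_patients must be a positive integer")
        if self.n_structured < 0 or self.n_nlp < 0:
            raise InvalidConfigError("feature counts must be non-negative")
        if self.n_features <= 0:
            raise InvalidConfigError("total feature count must be positive")
        if not self.outcome_spec:
            raise InvalidConfigError("outcome_spec must name at least one procedure")
        for proc, k in self.outcome_spec.items():
            if k < 0:
                raise InvalidConfigError(f"negative positive count for {proc!r}")
            if k > self.n_patients:
                raise InvalidConfigError(
                    f"positive count {k} for {proc!r} exceeds n_patients={self.n_patients}"
                )
        if not 0.0 <= self.signal_sparsity <= 1.0:
            raise InvalidConfigError("signal_sparsity must lie in [0, 1]")
        if self.interaction_pairs < 0:
            raise InvalidConfigError("interaction_pairs must be non-negative")
        if self.noise_scale < 0:
            raise InvalidConfigError("noise_scale must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outcome_spec"] = dict(self.outcome_spec)
        return d


@dataclass
class FeatureMatrix:
    """Design matrix with per-column provenance.

    ``feature_kind`` distinguishes ``structured`` columns, binary
    ``nlp_flag`` columns, and (after stage augmentation) ``stage_prob``
    columns carrying earlier-stage predicted probabilities.
    """

    values: np.ndarray
    feature_names: list[str]
    feature_kind: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match column count")
        if len(self.feature_kind) != len(self.feature_names):
            raise ValueError("feature_kind length does not match column count")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(), list(self.feature_names), list(self.feature_kind)
        )


@dataclass
class OutcomeLabels:
    """Binary outcome vectors, one per procedure."""

    labels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.labels = {p: np.asarray(v, dtype=int) for p, v in self.labels.items()}

    @property
    def procedures(self) -> tuple[str, ...]:
        return tuple(self.labels)

    def __getitem__(self, procedure: str) -> np.ndarray:
        return self.labels[procedure]

    def positive_counts(self) -> dict[str, int]:
        return {p: int(v.sum()) for p, v in self.labels.items()}


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def generate_cohort(config: CohortConfig) -> tuple[FeatureMatrix, OutcomeLabels]:
    """Generate a synthetic referral cohort.

    Returns the feature matrix (structured + NLP-flag columns) and one
    binary label vector per procedure with exactly the configured positive
    count. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, n_feat = config.n_patients, config.n_features

    # Structured block: first half binary history flags, second half
    # Poisson counts (appointments, medication orders).
    n_bin = config.n_structured // 2
    n_cnt = config.n_structured - n_bin
    cols: list[np.ndarray] = []
    names: list[str] = []
    kinds: list[str] = []
    if n_bin:
        p_flag = rng.uniform(0.02, 0.5, size=n_bin)
        cols.append((rng.random((n, n_bin)) < p_flag).astype(float))
        names += [f"struct_flag_{j:03d}" for j in range(n_bin)]
        kinds += ["structured"] * n_bin
    if n_cnt:
        lam = rng.uniform(0.3, 3.0, size=n_cnt)
        cols.append(rng.poisson(lam, size=(n, n_cnt)).astype(float))
        names += [f"struct_count_{j:03d}" for j in range(n_cnt)]
        kinds += ["structured"] * n_cnt
    if config.n_nlp:
        # Sparse concept flags: most concepts are rarely documented.
        p_nlp = rng.uniform(0.01, 0.25, size=config.n_nlp)
        cols.append((rng.random((n, config.n_nlp)) < p_nlp).astype(float))
        names += [f"nlp_concept_{j:03d}" for j in range(config.n_nlp)]
        kinds += ["nlp_flag"] * config.n_nlp

    X = np.hstack(cols)
    Z = _standardize(X)

    n_active = int(round(config.signal_sparsity * n_feat))
    if config.signal_sparsity > 0:
        n_active = max(n_active, 1)

    labels: dict[str, np.ndarray] = {}
    for proc, k_pos in config.outcome_spec.items():
        latent = np.zeros(n)
        if n_active:
            active = rng.choice(n_feat, size=n_active, replace=False)
            w = rng.normal(0.0, 1.0, size=n_active)
            latent += Z[:, active] @ w
            if config.interaction_pairs and n_active >= 2:
                for _ in range(config.interaction_pairs):
                    a, b = rng.choice(active, size=2, replace=False)
                    latent += rng.normal(0.0, 2.0) * Z[:, a] * Z[:, b]
        if config.noise_scale:
            latent += config.noise_scale * rng.normal(size=n)
        y = np.zeros(n, dtype=int)
        if k_pos:
            order = np.argsort(-latent, kind="stable")
            y[order[:k_pos]] = 1
        labels[proc] = y

    return FeatureMatrix(X, names, kinds), OutcomeLabels(labels)


# ---------------------------------------------------------------------------
# plain-text I/O

def write_cohort(
    features: FeatureMatrix,
    outcomes: OutcomeLabels,
    path: str | Path,
    config: CohortConfig | None = None,
) -> Path:
    """Write a cohort as CSV (one ``label_<PROCEDURE>`` column per outcome).

    When ``config`` is given, a sibling ``<stem>_config.yaml`` and
    ``<stem>_metadata.json`` record the configuration and seed.
    """
    path = Path(path)
    df = features.to_frame()
    for proc, y in outcomes.labels.items():
        df[f"label_{proc}"] = y
    df.to_csv(path, index=False)
    if config is not None:
        save_config(config, path.with_name(path.stem + "_config.yaml"))
        meta = {
            "seed": config.seed,
            "n_patients": features.n_patients,
            "n_features": features.n_features,
            "positive_counts": outcomes.positive_counts(),
        }
        path.with_name(path.stem + "_metadata.json").write_text(
            json.dumps(meta, indent=2)
        )
    return path


def read_cohort(path: str | Path) -> tuple[FeatureMatrix, OutcomeLabels]:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    label_cols = [c for c in df.columns if c.startswith("label_")]
    feat_cols = [c for c in df.columns if not c.startswith("label_")]
    kinds = ["nlp_flag" if c.startswith("nlp_") else "structured" for c in feat_cols]
    fm = FeatureMatrix(df[feat_cols].to_numpy(dtype=float), feat_cols, kinds)
    labels = {c[len("label_"):]: df[c].to_numpy(dtype=int) for c in label_cols}
    return fm, OutcomeLabels(labels)


def save_config(config: CohortConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> CohortConfig:
    d = yaml.safe_load(Path(path).read_text())
    return CohortConfig(**d)
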