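import numpy as np
import pytest

from paintriage import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient two-outcome cohort with planted signal."""
    cfg = CohortConfig(
        n_patients=300,
        n_structured=24,
        n_nlp=6,
        outcome_spec={"A": 30, "B": 15},
        signal_sparsity=0.2,
        interaction_pairs=3,
        noise_scale=0.5,
        seed=7,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def separable_toy():
    """20 points, one informative dimension, perfectly separable."""
    rng = np.random.default_rng(0)
    X = np.vstack(
        [
            np.column_stack([rng.normal(0, 0.3, 10), rng.normal(0, 1, 10)]),
            np.column_stack([rng.normal(5, 0.3, 10), rng.normal(0, 1, 10)]),
        ]
    )
    y = np.array([0] * 10 + [1] * 10)
    return X, y
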