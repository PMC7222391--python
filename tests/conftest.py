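"""Shared fixtures: small synthetic studies and hand-made tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mstnet import GroupSimConfig, generate_group
from mstnet.trial_io import CONDITIONS


@pytest.fixture(scope="session")
def small_study():
    """A 5-subject null study with short trials, shared across tests."""
    cfg = GroupSimConfig(
        n_subjects=5, trials_per_condition=1, duration=8.0, seed=1234
    )
    return generate_group(cfg)


def random_pli_matrix(rng: np.random.Generator, n: int = 32) -> np.ndarray:
    """A random symmetric matrix with zero diagonal and entries in [0, 1]."""
    a = rng.uniform(0, 1, size=(n, n))
    m = (a + a.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def hand_metric_table():
    """A frozen 6-subject single-metric table for the statistics oracles."""
    rng = np.random.default_rng(77)
    rows = []
    base = {"HAHV": 0.60, "HALV": 0.55, "LAHV": 0.45, "LALV": 0.44}
    for s in range(6):
        subject_effect = rng.normal(0, 0.05)
        for cond in CONDITIONS:
            rows.append(
                {
                    "subject_id": f"s{s}",
                    "condition": cond,
                    "band": "gamma",
                    "metric": "mpli",
                    "value": base[cond] + subject_effect + rng.normal(0, 0.03),
                }
            )
    return pd.DataFrame(rows)
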