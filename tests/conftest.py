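import numpy as np
import pandas as pd
import pytest

from covproj import DataTable, SyntheticConfig, generate_cohort
from covproj.simulate import pretreat_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def centered(rng, n, m):
    X = rng.standard_normal((n, m))
    return X - X.mean(axis=0)


@pytest.fixture
def small_table():
    """3-variable toy table with one covariate."""
    frame = pd.DataFrame(
        {
            "y": [1.2, 0.8, 1.5, 2.0, 0.9],
            "x1": [1.0, 2.0, 3.0, 4.0, 5.0],
            "x2": [2.0, 1.0, 2.5, 3.0, 1.5],
            "z": [0.5, 0.7, 0.6, 0.9, 0.4],
        },
        index=[f"s{i}" for i in range(5)],
    )
    return DataTable(
        frame=frame,
        roles={"y": "outcome", "x1": "explanatory", "x2": "explanatory", "z": "covariate"},
        groups={"z": "zgrp"},
    )


@pytest.fixture(scope="session")
def cohort():
    """One medium synthetic cohort, pretreated, shared across tests."""
    cfg = SyntheticConfig(n=600, seed=42)
    table, truth = generate_cohort(cfg)
    pre, state = pretreat_cohort(table)
    return pre, truth
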