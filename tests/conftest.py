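"""Shared fixtures: small simulated cohorts and toy survival data."""

import numpy as np
import pandas as pd
import pytest

from lncsurv import SimulationConfig, simulate_dataset
from lncsurv.datatypes import ExpressionMatrix, SurvivalOutcome


@pytest.fixture(scope="session")
def small_dataset():
    """500-subject, 30-gene cohort with 2 planted mains and a planted pair."""
    config = SimulationConfig(
        n_subjects=500,
        n_genes=30,
        n_informative_main=2,
        main_log_hr=0.6,
        interaction_log_hr=0.6,
        seed=42,
    )
    return simulate_dataset(config), config


@pytest.fixture(scope="session")
def null_dataset():
    """300-subject cohort with no gene effects at all."""
    config = SimulationConfig(
        n_subjects=300,
        n_genes=20,
        n_informative_main=0,
        interaction_log_hr=0.0,
        seed=7,
    )
    return simulate_dataset(config), config


@pytest.fixture
def toy_outcome():
    """Five uncensored subjects with distinct times."""
    return SurvivalOutcome(
        [f"s{i}" for i in range(5)],
        np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
        np.ones(5, dtype=int),
    )


def make_expression(values: np.ndarray, unit: str = "fpkm") -> ExpressionMatrix:
    g, n = values.shape
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"G{i:04d}" for i in range(g)],
            columns=[f"S{j:05d}" for j in range(n)],
        ),
        unit,
    )


@pytest.fixture
def expression_factory():
    return make_expression
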