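"""Shared fixtures: small synthetic cohorts with known ground truth.

All fixtures are seeded and session-scoped where fitting is expensive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gistnomo.prep import encode_dummies
from gistnomo.synthetic import CohortConfig, generate_raw_cohort

#: a compact ground-truth effect set used across model tests
TRUE_BETA = {
    "age_years": 0.04,
    "Sex_Male": 0.5,
    "Tumor_size_>=10 cm": 0.9,
    "AJCC_stage_IV": 0.8,
}


def signal_config(n: int = 1500, seed: int = 11, **kw) -> CohortConfig:
    """Cohort with known cancer-cause effects, no competing cause, and a
    baseline rate high enough for a healthy event fraction."""
    defaults = dict(
        n_patients=n,
        seed=seed,
        log_hazards_cancer=dict(TRUE_BETA),
        log_hazards_other={},
        other_cause_rate=0.0,
        baseline_hazard_rate=0.004,
        censor_rate=0.004,
    )
    defaults.update(kw)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def signal_cohort() -> pd.DataFrame:
    return generate_raw_cohort(signal_config())


@pytest.fixture(scope="session")
def encoded_ref(signal_cohort):
    return encode_dummies(signal_cohort, mode="reference")


@pytest.fixture(scope="session")
def encoded_full(signal_cohort):
    return encode_dummies(signal_cohort, mode="full")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def hand_survival():
    """Eight subjects with ties and censoring: a hand-checkable dataset."""
    time = np.array([2.0, 3.0, 3.0, 5.0, 7.0, 7.0, 9.0, 11.0])
    event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
    x = np.array([[1.0], [0.0], [1.0], [1.0], [0.0], [1.0], [0.0], [0.0]])
    return x, time, event
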