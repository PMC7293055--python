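import numpy as np
import pandas as pd
import pytest

from phenomarker import CohortConfig, generate_cohort
from phenomarker.ensemble import ModelOptions


def tiny_cohort_config(seed: int = 0, n: int = 8) -> CohortConfig:
    """Small, fast cohort: ~1.2 h of accelerometer, sparse comm streams."""
    return CohortConfig(n_participants=n, accel_days_cap=0.05,
                        duration_days_mean=4.0, duration_days_sd=0.5,
                        comm_rate_base=30.0, seed=seed)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(tiny_cohort_config())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_model_opts():
    """Light boosted-tree settings for contract-level tests whose outcome
    does not depend on the production hyperparameters."""
    return ModelOptions(n_estimators=50, seed=0)
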