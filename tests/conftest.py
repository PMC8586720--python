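import numpy as np
import pytest

from reachlearn.cohort import (
    CohortConfig,
    default_ground_truth,
    generate_cohort,
    generate_schedule,
)


@pytest.fixture(scope="session")
def ground_truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def noiseless_slice(ground_truth):
    """One noiseless subject x task phase under normal feedback."""
    cfg = CohortConfig(n_subjects=1, n_tasks=1, noise_sd=0.0,
                       ea_scheme="all_normal", seed=3)
    return generate_cohort(cfg).slices[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def schedule_250():
    return generate_schedule(250, rng=np.random.default_rng(7))
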