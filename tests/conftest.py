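import numpy as np
import pytest

from vfdna.cohort import run_pipeline
from vfdna.io import RunConfig
from vfdna.synthetic import generate_cohort


@pytest.fixture(scope="session")
def small_bundle():
    """A 30-sample synthetic cohort shared across tests."""
    return generate_cohort(n=30, rng_seed=7)


@pytest.fixture(scope="session")
def small_records(small_bundle):
    """Pipeline output for the shared cohort (reduced simulation depth)."""
    return run_pipeline(small_bundle, RunConfig(), rng_seed=7, n_sims=200)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
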