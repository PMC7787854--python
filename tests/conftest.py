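import numpy as np
import pytest

from t2drem.cohort import SyntheticCohortParams, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """An 87-patient cohort at the study's default conditions."""
    return generate_cohort(SyntheticCohortParams(n=87, seed=20201031))


@pytest.fixture(scope="session")
def large_cohort():
    """A 10k cohort for moment/correlation convergence checks."""
    return generate_cohort(SyntheticCohortParams(n=10_000, seed=20201031))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
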