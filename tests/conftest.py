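import numpy as np
import pytest

from actiqol import CohortConfig, run_study, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-parameter cohort shared across tests."""
    return simulate_cohort(CohortConfig(n_participants=120, seed=11))


@pytest.fixture(scope="session")
def small_study(small_cohort):
    return run_study(
        small_cohort.participants, small_cohort.streams, build_tables=False
    )


@pytest.fixture(scope="session")
def full_cohort():
    """A study-sized cohort (n = 1298) under the default conditions."""
    return simulate_cohort(CohortConfig(n_participants=1298, seed=20240903))


@pytest.fixture(scope="session")
def full_study(full_cohort):
    return run_study(
        full_cohort.participants, full_cohort.streams, build_tables=True
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(424242)
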