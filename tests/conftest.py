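import numpy as np
import pytest

from vpbci import ObserverParams, generate_cohort
from vpbci.cohort import CohortConfig


@pytest.fixture(scope="session")
def small_cohort():
    """A 3-per-group cohort for structural/IO tests (fast to build)."""
    return generate_cohort(CohortConfig(n_per_group=3), seed=123)


@pytest.fixture(scope="session")
def default_cohort():
    """Full 23-per-group cohort at generator defaults (no model fitting)."""
    return generate_cohort(seed=0)


@pytest.fixture
def typical_observer():
    return ObserverParams(sigma_v=3.0, sigma_p=8.0, p_prior=0.7)
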