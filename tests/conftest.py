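import numpy as np
import pytest

from nrquant import synthcohort as sc


@pytest.fixture(scope="session")
def small_cohort():
    """3k-patient default cohort shared across read-only tests."""
    return sc.generate_cohort(sc.CohortParams(n_patients=3000, seed=42))


@pytest.fixture(scope="session")
def big_cohort():
    """50k-patient cohort for marginal-rate checks."""
    return sc.generate_cohort(sc.CohortParams(n_patients=50_000, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
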