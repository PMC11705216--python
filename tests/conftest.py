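import numpy as np
import pytest

import seroblot as sb
from seroblot.synth import separable_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 8/8/8 synthetic cohort shared across tests."""
    return sb.generate_cohort(
        sb.CohortConfig(n_cancer=8, n_benign=8, n_healthy=8, seed=11)
    )


@pytest.fixture(scope="session")
def small_profiles(small_cohort):
    return sb.extract_cohort_profiles(small_cohort, seed=11)


@pytest.fixture(scope="session")
def separable_strips():
    """Trivially separable all-dark vs all-light 32x32 fixture."""
    return separable_cohort(n_per_class=18, size=32, seed=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
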