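import numpy as np
import pytest

from clotlab import synthetic as syn


@pytest.fixture(scope="session")
def default_cohort():
    """One deterministic default cohort (87 clots) shared across tests."""
    return syn.generate_cohort(seed=123)


@pytest.fixture(scope="session")
def default_cohort_table(default_cohort):
    return syn.cohort_table(default_cohort)


@pytest.fixture(scope="session")
def noise_free_cohort():
    return syn.generate_cohort(syn.DEFAULT_TRUTH.zero_noise(), seed=123)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
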