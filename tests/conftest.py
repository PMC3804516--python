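import pytest

from alemut.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (read-only)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig(seed=11)
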