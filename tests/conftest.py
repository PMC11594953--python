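import numpy as np
import pytest

from selfmanhf import generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient default-parameter cohort shared across read-only tests."""
    return generate_cohort(n=300, seed=42)
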