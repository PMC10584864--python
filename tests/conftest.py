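import numpy as np
import pytest

from lakenfix.synthetic import generate_expedition


@pytest.fixture(scope="session")
def expedition():
    """One deterministic synthetic transect shared across tests."""
    return generate_expedition(seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
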