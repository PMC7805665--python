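import numpy as np
import pytest

from ctseg.phantoms import PhantomConfig, generate_cases


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantoms():
    """Four deterministic 24^3 phantom cases for fast unit tests."""
    cfg = PhantomConfig(shape=(24, 24, 24))
    return generate_cases(4, cfg, seed=77)


@pytest.fixture(scope="session")
def default_phantom():
    """One case at the default 64^3 configuration."""
    cfg = PhantomConfig()
    return generate_cases(1, cfg, seed=3)[0]
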