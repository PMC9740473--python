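import numpy as np
import pytest

from mdem import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def dimer():
    return synthetic.make_test_dimer()


@pytest.fixture(scope="session")
def small_dimer():
    return synthetic.make_test_dimer(scale=0.5)


@pytest.fixture(scope="session")
def capsid():
    """Shared capsid fixture (expensive: ~1 min to build)."""
    return synthetic.capsid_fixture(seed=0)
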