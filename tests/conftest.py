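import numpy as np
import pytest

from plmmsa.encoder import ToyEncoder


@pytest.fixture(scope="session")
def toy():
    """Default toy encoder shared across tests."""
    return ToyEncoder(dim=64, k=3, seed=0)


@pytest.fixture(scope="session")
def align_encoder():
    """Higher-dimensional encoder used for residue-level alignment."""
    return ToyEncoder(name="align", dim=128, k=3, seed=303)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
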