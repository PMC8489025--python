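import numpy as np
import pytest

from hexnav import build_hexmaze


@pytest.fixture(scope="session")
def maze():
    return build_hexmaze()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
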