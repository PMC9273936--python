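import numpy as np
import pytest

from wtmm2d import synthesize_fbm


@pytest.fixture(scope="session")
def fbm_small():
    """One clean H=0.7 surface at modest size for structural tests."""
    return synthesize_fbm(0.7, 256, 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
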