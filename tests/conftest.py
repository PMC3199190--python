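import numpy as np
import pytest

import permfmri as pf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def block_paradigm():
    """20 s activity / 20 s rest over a 160 s scan."""
    return pf.Paradigm.block_design(on_s=20.0, off_s=20.0, duration_s=160.0)


@pytest.fixture(scope="session")
def design80(block_paradigm):
    """Two-regressor design for 80 volumes at TR 2 s."""
    return pf.build_design(block_paradigm, nt=80, tr=2.0)
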