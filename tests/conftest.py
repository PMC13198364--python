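import logging

import numpy as np
import pytest

logging.getLogger("otalign").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_instance(rng):
    """A fixed 5x5 balanced OT instance with costs in [0, 1]."""
    C = rng.random((5, 5))
    return C
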