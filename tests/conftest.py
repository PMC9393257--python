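import logging

import numpy as np
import pytest

from crossmodal.auditory import EardrumFilterSpec
from crossmodal.world import AcousticParams

logging.getLogger("crossmodal").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def acoustics():
    return AcousticParams()


@pytest.fixture(scope="session")
def filter_spec():
    return EardrumFilterSpec()
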