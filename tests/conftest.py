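import numpy as np
import pytest

from mazeskill.config import SegmentationParams
from mazeskill.maze import default_layout


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def params():
    return SegmentationParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
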