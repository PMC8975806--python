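import numpy as np
import pytest

from forktrap import CameraModel


@pytest.fixture
def camera32():
    return CameraModel.ideal((32, 32))


@pytest.fixture
def camera9():
    return CameraModel.ideal((9, 9))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
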