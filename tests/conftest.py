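import numpy as np
import pytest

from paintdense import CameraModel


@pytest.fixture
def camera() -> CameraModel:
    return CameraModel(offset=100.0, gain=1.0, read_noise=1.0, pixel_size=107.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
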