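import numpy as np
import pytest

from tricorr.io import Canvas, LocalizationSet


@pytest.fixture
def canvas() -> Canvas:
    return Canvas(0.0, 1000.0, 0.0, 1000.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_set(channel: str, xy, canvas: Canvas, sigma=None) -> LocalizationSet:
    return LocalizationSet(channel=channel, xy=np.asarray(xy, float), canvas=canvas, sigma=sigma)
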