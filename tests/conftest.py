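import numpy as np
import pytest

from greenpoly.color import hsv_to_rgb


def flat_hsv_crop(h, s, v, shape=(40, 40)):
    """RGB crop whose every pixel has the given HSV byte values."""
    hsv = np.zeros((*shape, 3), dtype=float)
    hsv[..., 0] = h
    hsv[..., 1] = s
    hsv[..., 2] = v
    return hsv_to_rgb(hsv)


@pytest.fixture
def green_crop():
    return flat_hsv_crop(60, 200, 150)


@pytest.fixture
def soil_crop():
    # brown: hue ~14, well below the green band floor
    return flat_hsv_crop(14, 120, 110)
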