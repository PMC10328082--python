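import numpy as np
import pytest

from histoquant.imaging_io import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack(rng):
    """2-channel, 4-slice, 16x16 random uint16 stack with calibration."""
    data = rng.integers(0, 1000, size=(2, 4, 16, 16)).astype(np.uint16)
    return ImageStack(data, pixel_size_um=0.25, z_step_um=0.5, channel_names=("old", "new"))


def make_stack(data, pixel_size_um=0.25, z_step_um=0.5, names=None):
    data = np.asarray(data)
    if names is None:
        names = tuple(f"ch{i}" for i in range(data.shape[0]))
    return ImageStack(data, pixel_size_um, z_step_um, names)
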