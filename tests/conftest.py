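import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def square_mask(shape, center, half):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (np.abs(xx - center[0]) <= half) & (np.abs(yy - center[1]) <= half)


@pytest.fixture
def disk_phantom():
    """Clean two-region 64x64 disk phantom: inside 0.8, outside 0.2."""
    mask = disk_mask((64, 64), (32, 32), 14)
    return np.where(mask, 0.8, 0.2), mask


@pytest.fixture
def noisy_disk_phantom(disk_phantom, rng):
    frame, mask = disk_phantom
    return np.clip(frame + 0.1 * rng.normal(size=frame.shape), 0, 1), mask
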