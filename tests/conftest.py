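import numpy as np
import pytest

from seglink.crosslink import link_slice
from seglink.label_model import LinkedStackState


def disk_mask(shape, cy, cx, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_base_slice(rng, shape=(24, 24), n_blobs=4):
    """A small labeled slice of disjoint rectangular blobs."""
    base = np.zeros(shape, dtype=np.int32)
    label = 1
    for _ in range(n_blobs):
        h, w = rng.integers(2, 6, size=2)
        y = rng.integers(0, shape[0] - h)
        x = rng.integers(0, shape[1] - w)
        region = base[y : y + h, x : x + w]
        if (region != 0).any():
            continue
        region[:] = label
        label += 1
    return base


@pytest.fixture
def small_state(rng):
    """A 3-slice linked stack built from random blob slices."""
    state = LinkedStackState(history_capacity=10)
    for _ in range(3):
        link_slice(state, random_base_slice(rng))
    return state
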