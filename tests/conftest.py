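import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dualpet.volume import ScalarVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_blob_mask(rng, shape=(20, 20, 20), n_blobs=3, r_range=(2, 4)):
    """Random spherical blob mask on a small grid (voxel units)."""
    mask = np.zeros(shape, dtype=np.uint8)
    grid = np.indices(shape).reshape(3, -1).T
    for _ in range(n_blobs):
        c = rng.uniform(2, np.asarray(shape) - 2)
        r = rng.uniform(*r_range)
        d2 = ((grid - c) ** 2).sum(axis=1)
        mask.ravel()[d2 <= r**2] = 1
    return mask


def as_volume(arr, spacing=(1.0, 1.0, 1.0), units="binary"):
    return ScalarVolume(arr, spacing, (0.0, 0.0, 0.0), units)
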