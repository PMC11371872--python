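import numpy as np
import pytest

from mtlpath.heatmap import SamplingBox
from mtlpath.simulate import generate_cohort


@pytest.fixture(scope="session")
def cohort140():
    """Study-sized synthetic cohort with default planted effects."""
    return generate_cohort(140, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_walk_mask(n_pixels: int, shape=(60, 60), seed: int = 0):
    """Irregular connected blob grown by a random walk."""
    rng = np.random.default_rng(seed)
    m = np.zeros(shape, bool)
    r, c = shape[0] // 2, shape[1] // 2
    while m.sum() < n_pixels:
        m[r, c] = True
        dr, dc = rng.choice([(-1, 0), (1, 0), (0, -1), (0, 1)])
        r = int(np.clip(r + dr, 1, shape[0] - 2))
        c = int(np.clip(c + dc, 1, shape[1] - 2))
    return m


@pytest.fixture()
def blob_box():
    """1,000-pixel irregular blob at 1 um/px."""
    return SamplingBox("blob", "slide0", "CA1",
                       random_walk_mask(1000, seed=3), pixel_size_um=1.0)
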