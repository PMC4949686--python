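import numpy as np
import pytest

from rhizotrace.levelset import LevelSetField


@pytest.fixture
def disc_field():
    """Factory for a disc-shaped level-set field on a given frame."""

    def make(target_id=1, plant_id=1, shape=(64, 64), center=(32, 32), radius=20.0):
        return LevelSetField.from_disc(target_id, plant_id, shape, center, radius)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def disc_mask(shape, center, radius):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


@pytest.fixture
def make_disc_mask():
    return disc_mask
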