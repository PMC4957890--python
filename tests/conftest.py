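import numpy as np
import pytest
from hypothesis import settings

from parenkin.kinetics import DCESeries, SegmentationMasks

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

TIMES = np.array([0.0, 1.5, 4.5, 7.5])
SPACING = np.array([1.0, 1.0, 2.0])


def random_series(rng: np.random.Generator, shape=(8, 8, 4)) -> DCESeries:
    """Random positive DCE series on a small grid."""
    signal = rng.uniform(50.0, 500.0, size=(4,) + shape)
    return DCESeries(signal=signal, times_min=TIMES, voxel_spacing_mm=SPACING)


def full_masks(shape=(8, 8, 4)) -> SegmentationMasks:
    m = np.ones(shape, dtype=bool)
    return SegmentationMasks(breast=m, fgt=m.copy())


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160722)


@pytest.fixture
def series8(rng) -> DCESeries:
    return random_series(rng)


@pytest.fixture
def masks8() -> SegmentationMasks:
    return full_masks()
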