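import numpy as np
import pytest

from axopath.image_ops import ImageStack
from axopath.synthetic import CohortSimConfig, ImageSimConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_stack(rng):
    """An uncorrelated 8-bit noise stack with default calibration."""
    voxels = rng.integers(0, 256, size=(4, 32, 32), dtype=np.uint8)
    return ImageStack(voxels=voxels, bit_depth=8, pixel_size=0.1, z_step=1.0)


@pytest.fixture
def default_image_config():
    return ImageSimConfig(seed=7, render="brightfield")


@pytest.fixture
def default_cohort():
    return generate_cohort(CohortSimConfig(seed=11))
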