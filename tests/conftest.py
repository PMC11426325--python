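import numpy as np
import pytest

from sargmap.raster_io import DEFAULT_PALETTE
from sargmap.synthetic import SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def palette():
    return DEFAULT_PALETTE


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 256x256 synthetic beach scene with ground truth."""
    return generate_scene(SceneConfig(height=256, width=256, seed=7))
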