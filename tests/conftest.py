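import numpy as np
import pytest

from inflocount import SceneParams, generate_scene

# small, fast scene used by most integration-style tests
SMALL_PARAMS = SceneParams(
    image_size=(480, 640),
    n_flowers=20,
    seed=11,
)


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(SMALL_PARAMS)


@pytest.fixture(scope="session")
def default_scene():
    """One scene at the shipped benchmark difficulty."""
    return generate_scene(SceneParams(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
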