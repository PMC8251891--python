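import numpy as np
import pytest

from livernav import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def scene():
    """One reference phantom scene shared by read-only tests."""
    return generate_scene(SceneConfig(), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
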