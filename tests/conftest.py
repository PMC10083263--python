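import numpy as np
import pytest

from cropsignal import SceneConfig, SensorArray


@pytest.fixture(scope="session")
def array():
    return SensorArray()


@pytest.fixture(scope="session")
def clean_config():
    """Default generator settings: no jitter, well-separated plants."""
    return SceneConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230327)


def random_mask(rng, shape, p=0.5):
    return np.where(rng.random(shape) < p, 255, 0).astype(np.uint8)
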