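import numpy as np
import pytest

from stripedet.synthetic import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    spec = SceneSpec(image_size=128, n_objects=(3, 3), seed=5)
    return generate_scene(spec)
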