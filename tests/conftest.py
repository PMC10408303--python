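import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from weednet.model import ModelConfig, build_model
from weednet.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def tiny_model():
    """Small detector shared by shape/decoding tests (weights untrained)."""
    return build_model(
        ModelConfig(backbone="tiny", fpn_channels=32, head_convs=1), seed=0
    )


@pytest.fixture(scope="session")
def small_scene():
    return generate_scene(SceneSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
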