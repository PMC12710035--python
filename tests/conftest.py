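import numpy as np
import pytest

from podkit import SceneConfig, easy_scene_config, generate_scene


@pytest.fixture(scope="session")
def easy_scenes():
    """32 easy scenes: large, disjoint, unoccluded pods on a clean backdrop."""
    return [generate_scene(easy_scene_config(100 + i)) for i in range(32)]


@pytest.fixture(scope="session")
def dense_scene():
    """One default dense scene with occluders."""
    return generate_scene(SceneConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
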