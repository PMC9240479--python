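import numpy as np
import pytest
from hypothesis import settings

from weedseg.synthetic import SceneSpec, generate_scene, strip_broadleaf

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_pairs():
    """Eight dense 64x64 scenes with network-facing (3-class) masks."""
    pairs = []
    for s in range(8):
        img, mask = generate_scene(SceneSpec(
            size=64, n_soybean=3, n_grass=3, n_broadleaf=1,
            plant_scale=0.5, seed=100 + s))
        pairs.append((img, strip_broadleaf(mask)))
    return pairs


@pytest.fixture(scope="session")
def demo_scene():
    """One 256x256 scene with full four-class ground truth."""
    return generate_scene(SceneSpec(size=256, seed=7))
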