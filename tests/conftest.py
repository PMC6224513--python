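import numpy as np
import pytest

from mito3d.synthetic_data import SceneConfig, generate_scene
from mito3d.volume import VoxelSpacing


@pytest.fixture(scope="session")
def default_scene():
    """One deterministic synthetic scene shared across read-only tests."""
    return generate_scene(SceneConfig(), seed=7)


@pytest.fixture(scope="session")
def small_scene():
    """A smaller, quicker scene for pipeline-level tests."""
    cfg = SceneConfig(shape=(12, 64, 64), n_objects=(2, 3))
    return generate_scene(cfg, seed=21)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def iso10():
    return VoxelSpacing(10.0, 10.0, 10.0)
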