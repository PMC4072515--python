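import numpy as np
import pytest

from conelearn.mosaic import ConeClassSpec, build_mosaic
from conelearn.scenes import SceneModel, generate_scene
from conelearn.spectra import standard_set

LM_SPECS = [ConeClassSpec("L", 558.9), ConeClassSpec("M", 530.0)]


@pytest.fixture(scope="session")
def fundamentals():
    return standard_set()


@pytest.fixture(scope="session")
def lm_mosaic():
    """A 10x10 L:M 1:1 mosaic with 6% S cones."""
    return build_mosaic(10, LM_SPECS, [1.0, 1.0], s_fraction=0.06, seed=3)


@pytest.fixture(scope="session")
def tiny_scenes():
    """Three small synthetic scenes for sampling tests."""
    return [generate_scene(SceneModel(size=32, seed=s)) for s in range(3)]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
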