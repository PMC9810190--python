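import numpy as np
import pytest

from germcount import SceneSpec, generate_scene, run_pipeline


@pytest.fixture(scope="session")
def default_scene():
    """One routine scene (40 grains, 28 germinated) with its pipeline result."""
    spec = SceneSpec(seed=3, n_grains=40)
    img, truth = generate_scene(spec)
    result = run_pipeline(img)
    return spec, img, truth, result


@pytest.fixture(scope="session")
def small_scene():
    """A fast scene for end-to-end plumbing tests (no clusters)."""
    spec = SceneSpec(seed=9, n_grains=10, adhesion_fraction=0.0, image_size=(560, 560))
    img, truth = generate_scene(spec)
    return spec, img, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
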