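import numpy as np
import pytest

from bioflow import chamber, synth


@pytest.fixture(scope="session")
def soil_layout():
    """One representative soil-mimic layout (fixed seed, default chamber)."""
    return chamber.generate_soil_layout(seed=1)


@pytest.fixture(scope="session")
def clean_scene(soil_layout):
    """Noise-free two-channel scene with ground truth and tessellation."""
    params = synth.SceneParams(noise=False)
    image, truth, tess = synth.render_chamber_scene(soil_layout, params, seed=11)
    return image, truth, tess


@pytest.fixture(scope="session")
def noisy_scene(soil_layout):
    """Default-SNR scene with Poisson-Gaussian noise."""
    params = synth.SceneParams()
    image, truth, tess = synth.render_chamber_scene(soil_layout, params, seed=21)
    return image, truth, tess


@pytest.fixture(scope="session")
def clean_bead_stack(clean_scene):
    _, truth, tess = clean_scene
    return synth.render_bead_stack(tess, truth, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
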