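import numpy as np
import pytest

from holocyte import phantom
from holocyte.forward import OpticalConfig, object_wave, record_hologram, reference_wave


@pytest.fixture(scope="session")
def sealed_base():
    """Reference-temperature phantom of the sealed-chamber scenario."""
    return phantom.scenario_base_params(phantom.sealed_scenario())


@pytest.fixture(scope="session")
def small_scene(sealed_base):
    """Single cell on a 256^2 grid at 0.36 um pitch (fast unit-test scene)."""
    cfg = phantom.SceneConfig(grid_size=256, pixel_pitch_um=0.36, n_cells=1)
    return phantom.render_scene([sealed_base], cfg), cfg


@pytest.fixture(scope="session")
def midsize_hologram(sealed_base):
    """Noise-free off-axis hologram of one cell on a 512^2 grid."""
    cfg = phantom.SceneConfig(grid_size=512, pixel_pitch_um=0.18, n_cells=1)
    scene = phantom.render_scene([sealed_base], cfg)
    optics = OpticalConfig(pixel_pitch_um=0.18)
    obj = object_wave(scene, optics)
    ref = reference_wave(optics, scene.shape)
    return record_hologram(obj, ref, optics), scene, optics
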