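import numpy as np
import pytest

from dropwet.fluids import WATER, BACTERIA_OD10
from dropwet.synthetic import SyntheticScene, gen_sessile_image


@pytest.fixture(scope="session")
def default_scene():
    return SyntheticScene()


@pytest.fixture(scope="session")
def standard_drop(default_scene):
    """Noiseless 35 uL / 40 deg water drop: (image, ground truth)."""
    return gen_sessile_image(35.0, 40.0, WATER, default_scene)


@pytest.fixture(scope="session")
def fine_scene():
    """Finer pixel scale for shallow or small drops."""
    return SyntheticScene(pixel_scale=0.008, image_size=(480, 1100), baseline_row=420)


@pytest.fixture(scope="session")
def evap_pipeline_scene():
    """Scene keeping late (shallow) evaporation frames measurable."""
    return SyntheticScene(pixel_scale=0.010, image_size=(480, 1000), baseline_row=420)
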