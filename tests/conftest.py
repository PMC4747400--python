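import numpy as np
import pytest

from ihcmorph import AnalysisConfig, RGBImage


@pytest.fixture
def default_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def white_image() -> RGBImage:
    return RGBImage(np.full((32, 32, 3), 255, dtype=np.uint8), 255.0)


@pytest.fixture
def small_scene():
    """A 400x400 field of 20 well-separated nuclei with ground truth."""
    from ihcmorph import random_scene, render_scene

    scene = random_scene(n_cells=20, image_size=(400, 400), seed=3)
    image, truth = render_scene(scene)
    return scene, image, truth
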