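import numpy as np
import pytest

from wbcseg import RasterImage, SmearSceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def default_scene():
    """One seeded synthetic smear under generator defaults (mild blur/noise)."""
    return generate_scene(SmearSceneConfig(seed=7))


@pytest.fixture
def clean_scene():
    """Same scene geometry with degradations switched off."""
    return generate_scene(SmearSceneConfig(seed=7, blur_sigma=0.0, noise_sd=0.0))


def make_rgb(arr):
    return RasterImage(np.asarray(arr, dtype=np.uint8), "RGB")
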