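import dataclasses

import numpy as np
import pytest

from seedhsi.calibrate import ReferencePair, correct_reflectance
from seedhsi.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    """Compact scene used by most image-level tests."""
    return SceneConfig(image_height=72, image_width=96, n_seeds_per_class=2, rng_seed=11)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture(scope="session")
def noiseless_config(small_config) -> SceneConfig:
    return dataclasses.replace(small_config, noise_sd=0.0, illumination_gradient=0.0, rng_seed=12)


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_config):
    return generate_scene(noiseless_config)


@pytest.fixture(scope="session")
def corrected_small(small_scene):
    raw, dark, white, truth = small_scene
    return correct_reflectance(raw, ReferencePair(dark=dark, white=white)), truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
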