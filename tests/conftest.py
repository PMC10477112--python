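import dataclasses

import numpy as np
import pytest

from plaquant.synthetic import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_clean_spec() -> SceneSpec:
    """Small noise-free scene with one full-stack nucleus and sparse dots."""
    return SceneSpec(shape=(12, 96, 96), n_nuclei=1, nucleus_radii=(8.0, 30.0, 30.0),
                     n_pla_dots=40, n_organelles=0,
                     poisson_gain=0.0, gaussian_noise_sigma=0.0, seed=11)


@pytest.fixture(scope="session")
def small_clean_scene(small_clean_spec):
    return generate_scene(small_clean_spec)


@pytest.fixture(scope="session")
def small_noisy_scene(small_clean_spec):
    spec = dataclasses.replace(small_clean_spec, poisson_gain=1.0,
                               gaussian_noise_sigma=3.0, seed=12)
    return generate_scene(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
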