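import dataclasses

import numpy as np
import pytest

from tjmorph import SceneParams, generate_junction_scene


@pytest.fixture(scope="session")
def small_scene_params() -> SceneParams:
    """A quick-to-render scene used across tests."""
    return SceneParams(
        field_size_px=(512, 512),
        pixel_size_um=0.04,
        n_cells=8,
        ruffle_wavelength_um=2.0,
        ruffle_amplitude_um=0.3,
        noise_model="poisson",
        seed=11,
    )


@pytest.fixture(scope="session")
def small_scene(small_scene_params):
    return generate_junction_scene(small_scene_params)


@pytest.fixture(scope="session")
def noise_free_scene(small_scene_params):
    return generate_junction_scene(
        dataclasses.replace(small_scene_params, noise_model="none", seed=3)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
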