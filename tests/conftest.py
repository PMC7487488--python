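import numpy as np
import pytest
import trimesh

from femwba import FemurParams, generate_femur_surface, generate_radiograph


@pytest.fixture(scope="session")
def femur_default():
    """Default synthetic femur surface + ground truth (moderate resolution)."""
    params = FemurParams()
    mesh, truth = generate_femur_surface(params, pitch=1.5)
    return params, mesh, truth


@pytest.fixture(scope="session")
def radiograph_noise_free(femur_default):
    """Noise-free magnified radiograph of the default femur (CE 33 deg)."""
    _, _, truth = femur_default
    return generate_radiograph(
        truth, magnification=1.1, noise_sd=0.0, seed=0, target_ce_deg=33.0
    )


@pytest.fixture(scope="session")
def unit_sphere():
    """Unit icosphere with ~20k facets (vertices exactly on the sphere)."""
    return trimesh.creation.icosphere(subdivisions=5, radius=1.0)


@pytest.fixture(scope="session")
def unit_sphere_coarse():
    return trimesh.creation.icosphere(subdivisions=4, radius=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
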