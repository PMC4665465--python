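"""Shared fixtures: phantom geometry, gantry and reusable noiseless acquisitions."""

import numpy as np
import pytest

from mblt import (
    MEDIA,
    GantryConfig,
    PointSource,
    SceneModel,
    build_cylinder_phantom,
    build_gantry,
    simulate_acquisition,
)

PHANTOM_POWER = 1.4e10  # photons/s


@pytest.fixture(scope="session")
def phantom():
    """Default 30 mm Intralipid cylinder: (grid, mesh, inside-mask)."""
    return build_cylinder_phantom(30.0, 40.5, 0.5)


@pytest.fixture(scope="session")
def lipid():
    return MEDIA["intralipid_1pct_560nm"]


@pytest.fixture(scope="session")
def air():
    return MEDIA["air"]


@pytest.fixture(scope="session")
def poses():
    """The full 20-view gantry (4 cameras, 18 degree steps)."""
    return build_gantry(GantryConfig())


@pytest.fixture(scope="session")
def offaxis_lipid_views(phantom, lipid, poses):
    """Noiseless 20-view acquisition of a fiber 10 mm off-center in Intralipid."""
    _, mesh, _ = phantom
    scene = SceneModel(mesh, lipid, [PointSource((10.0, 0.0, 0.0), PHANTOM_POWER)])
    return simulate_acquisition(scene, poses, exposure_s=60.0, noise=False)


@pytest.fixture(scope="session")
def offaxis_air_views(phantom, air, poses):
    """The same fiber imaged bare (no scattering medium)."""
    _, mesh, _ = phantom
    scene = SceneModel(mesh, air, [PointSource((10.0, 0.0, 0.0), PHANTOM_POWER)])
    return simulate_acquisition(scene, poses, exposure_s=60.0, noise=False)
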