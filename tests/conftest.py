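import numpy as np
import pytest

from orbitmech import (
    MaterialParams,
    PhantomSpec,
    build_tet_mesh,
    generate_phantom,
    simulate_scenario,
)
from orbitmech.pipeline import default_lava_plan, default_twowall_plan


@pytest.fixture(scope="session")
def phantom_default():
    """Default synthetic orbit at 1 mm voxels, with analytic ground truth."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def mesh_fine(phantom_default):
    vol, gt = phantom_default
    return build_tet_mesh(vol, ground_truth=gt)  # pitch = voxel size


@pytest.fixture(scope="session")
def mesh_te2(phantom_default):
    vol, gt = phantom_default
    return build_tet_mesh(vol, target_edge=2.0, ground_truth=gt)


@pytest.fixture(scope="session")
def mesh_te4(phantom_default):
    vol, gt = phantom_default
    return build_tet_mesh(vol, target_edge=4.0, ground_truth=gt)


@pytest.fixture(scope="session")
def materials():
    return MaterialParams.orbital_defaults()


@pytest.fixture(scope="session")
def lava_result(phantom_default, mesh_te2, materials):
    vol, _ = phantom_default
    return simulate_scenario(
        mesh_te2, default_lava_plan(), materials, n_steps=10, obstacle=vol
    )


@pytest.fixture(scope="session")
def twowall_result(phantom_default, mesh_te2, materials):
    vol, _ = phantom_default
    return simulate_scenario(
        mesh_te2, default_twowall_plan(), materials, n_steps=10, obstacle=vol
    )
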