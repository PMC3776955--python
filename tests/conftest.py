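"""Shared fixtures: phantom geometry, session data, surface models.

Everything is generated programmatically at test time; expensive artifacts
(meshes, simulated sessions) are session-scoped.
"""

import numpy as np
import pytest

from tonodepth.phantom import (
    PhantomSpec,
    make_phantom_mask,
    make_session_design,
    plant_frequency_field,
    simulate_session,
)
from tonodepth.response import extract_amplitudes, resample_to_mask
from tonodepth.surface import (
    compute_depth_map,
    curvature_and_region,
    extract_surface,
)


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def phantom(default_spec):
    """Default phantom: functional + structural masks, ground truth."""
    func = make_phantom_mask(default_spec)
    struct = make_phantom_mask(
        default_spec, voxel_size_mm=default_spec.surface_voxel_size_mm
    )
    gt = plant_frequency_field(func, default_spec)
    return func, struct, gt


@pytest.fixture(scope="session")
def phantom_surface(phantom):
    """Surface model and structural-grid depth map of the default phantom."""
    _, struct, _ = phantom
    surf = extract_surface(struct.mask, struct.voxel_size_mm, smoothing_iters=20)
    curvature_and_region(surf)
    depthmap = compute_depth_map(struct.mask, surf, struct.voxel_size_mm)
    return surf, depthmap


@pytest.fixture(scope="session")
def phantom_responses(phantom, default_spec):
    """Quiet-referenced responses of one simulated session, on the
    structural analysis grid."""
    _, struct, gt = phantom
    data = simulate_session(gt, default_spec)
    return extract_amplitudes(resample_to_mask(data, struct))


@pytest.fixture(scope="session")
def sphere_surface():
    """Digitized sphere, r = 10 mm at 0.5-mm voxels."""
    vs, n, r = 0.5, 46, 10.0
    ax = (np.arange(n) + 0.5) * vs
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    c = n * vs / 2
    mask = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= r * r
    surf = extract_surface(mask, vs, smoothing_iters=20)
    return surf, c, r


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast phantom for pipeline smoke tests."""
    return PhantomSpec(
        grid_shape=(20, 14, 12),
        colliculus_radii_mm=((2.4, 2.4, 2.4), (2.4, 2.4, 2.4)),
        cap_gap_mm=1.2,
        n_runs=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def design(default_spec):
    return make_session_design(default_spec)
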