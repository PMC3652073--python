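"""Shared fixtures: phantoms, meshes and fitted registrations.

Heavy artifacts (phantom pairs, evolutions, fitted registrations) are
session-scoped and reused across test modules; all randomness is seeded.
"""

import numpy as np
import pytest

from ffdreg import (
    ActiveSurfaceParams,
    PhantomSpec,
    SurfaceRegistration,
    apply_ground_truth_deformation,
    compute_edge_map,
    extract_surface,
    make_phantom,
)
from ffdreg.ffd import init_grid
from ffdreg.phantom import smooth_control_displacement

SPHERE_CENTER = np.array([32.0, 32.0, 32.0])
SPHERE_RADIUS = 20.0


@pytest.fixture(scope="session")
def sphere_phantom():
    """64^3 sphere phantom (radius 20 mm, contrast 150, noise sd 5)."""
    spec = PhantomSpec(
        shape="ellipsoid",
        semi_axes_mm=(SPHERE_RADIUS,) * 3,
        center_mm=tuple(SPHERE_CENTER),
        noise_sd=5.0,
        seed=1,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def sphere_mesh(sphere_phantom):
    _, mask = sphere_phantom
    return extract_surface(mask)


@pytest.fixture(scope="session")
def sphere_evolution(sphere_phantom, sphere_mesh):
    """Evolve the sphere surface from a 5-voxel outward radial offset."""
    vol, _ = sphere_phantom
    edge_map = compute_edge_map(vol, 2.0)
    r = np.linalg.norm(sphere_mesh.vertices - SPHERE_CENTER, axis=1)
    offset = SPHERE_CENTER + (sphere_mesh.vertices - SPHERE_CENTER) * ((r + 5.0) / r)[:, None]
    init = sphere_mesh.with_vertices(offset)
    params = ActiveSurfaceParams()
    adapted, trace = ffdreg_evolve(init, edge_map, params)
    return adapted, trace, params, edge_map


def ffdreg_evolve(mesh, edge_map, params):
    from ffdreg import evolve

    return evolve(mesh, edge_map, params)


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    """64^3 ellipsoid phantom (semi-axes 20/15/12 mm, noise sd 5)."""
    spec = PhantomSpec(
        shape="ellipsoid",
        semi_axes_mm=(20.0, 15.0, 12.0),
        center_mm=(32.0, 32.0, 32.0),
        noise_sd=5.0,
        seed=2,
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def gt_deformation(ellipsoid_phantom):
    """Ground-truth smooth FFD warp of the ellipsoid phantom (amp 4 mm)."""
    vol, mask = ellipsoid_phantom
    lo, hi = vol.bounds()
    grid = init_grid(lo, hi, 5, 5, 5, margin=0.0)
    disp = smooth_control_displacement(grid, 4.0, seed=12)
    dvol, dmask, dense = apply_ground_truth_deformation(vol, mask, grid, disp)
    return {
        "grid": grid,
        "control_displacement": disp,
        "deformed_vol": dvol,
        "deformed_mask": dmask,
        "dense_field": dense,
    }


@pytest.fixture(scope="session")
def registration_fit(ellipsoid_phantom, gt_deformation):
    """Registration of the original phantom onto its deformed copy."""
    vol, mask = ellipsoid_phantom
    model = SurfaceRegistration(vol, mask, gt_deformation["deformed_vol"])
    return model.fit()


@pytest.fixture(scope="session")
def icosahedron():
    import trimesh.creation

    from ffdreg.mesh import SurfaceMesh

    tm = trimesh.creation.icosahedron()
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
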