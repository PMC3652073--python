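"""Active-surface evolution: force balance on an inverse edge map.

The mesh evolves by explicit time stepping
``v <- v + tau(t) * (alpha*F_elastic + beta*F_rigid + kappa*F_ext)`` until the
mean vertex increment falls below a tolerance.  Internal forces are discrete:
the elastic (tensile) force is the umbrella operator — the mean of the 1-ring
minus the vertex — and the rigid (bending) force is minus the umbrella
operator applied twice, a linear combination of tensile forces over the
2-ring.  The external force is the negative gradient of the edge potential,
so the surface descends into the edge minima.  The step scale ``tau(t)`` is
renormalised every iteration so that no vertex moves more than a fixed
fraction of the smallest voxel spacing (a CFL-type stability bound).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
from scipy import ndimage

from .errors import EvolutionError
from .mesh import SurfaceMesh
from .volume import EdgeMap

__all__ = [
    "ActiveSurfaceParams",
    "EvolutionTrace",
    "elastic_force",
    "rigid_force",
    "external_force",
    "evolve",
]


@dataclass
class ActiveSurfaceParams:
    """Weights and stepping controls for the surface evolution.

    alpha, beta, kappa : weights of the elastic, rigid and external forces
        (dimensionless, >= 0).
    tau_max : upper bound on the step scale (mm per unit force).
    cfl_fraction : maximum allowed vertex displacement per step, as a
        fraction of the smallest voxel spacing (0 < cfl_fraction <= 1).
    max_iters : iteration cap.
    tol : convergence threshold on the mean vertex increment in mm.
    self_intersection_every : run the sampled self-intersection check every
        this many iterations (0 disables it).
    """

    alpha: float = 0.3
    beta: float = 0.1
    kappa: float = 1.0
    tau_max: float = 1.0
    cfl_fraction: float = 0.5
    max_iters: int = 500
    tol: float = 1e-3
    self_intersection_every: int = 10

    def __post_init__(self):
        if min(self.alpha, self.beta, self.kappa) < 0:
            raise ValueError("force weights must be >= 0")
        if not 0 < self.cfl_fraction <= 1:
            raise ValueError("cfl_fraction must be in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class EvolutionTrace:
    """Per-iteration record of the evolution."""

    mean_increment: list = field(default_factory=list)   # mm
    max_increment: list = field(default_factory=list)    # mm
    energy: list = field(default_factory=list)           # mean potential at vertices
    out_of_bounds: list = field(default_factory=list)    # clamped vertex count
    iterations: int = 0
    converged: bool = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "mean_increment_mm": self.mean_increment,
            "max_increment_mm": self.max_increment,
            "energy": self.energy,
            "out_of_bounds": self.out_of_bounds,
        })


def _ring_mean(mesh: SurfaceMesh, values: np.ndarray) -> np.ndarray:
    """Mean of `values` over each vertex's 1-ring (vectorised)."""
    nbrs, off = mesh.adjacency
    sums = np.add.reduceat(values[nbrs], off[:-1], axis=0)
    counts = np.diff(off)
    # reduceat yields the next segment's first element for empty segments;
    # extraction guarantees nonempty rings, so counts > 0 here.
    return sums / counts[:, None]


def elastic_force(mesh: SurfaceMesh, vertex_index: int | None = None) -> np.ndarray:
    """Umbrella tensile force: mean 1-ring position minus the vertex.

    ``F_elastic(i) = sum_{j in ring(i)} (v_j - v_i) / |ring(i)|``; zero when
    the vertex sits at its neighbours' centroid.  Without an index, returns
    the (N, 3) force field.
    """
    forces = _ring_mean(mesh, mesh.vertices) - mesh.vertices
    return forces if vertex_index is None else forces[vertex_index]


def rigid_force(mesh: SurfaceMesh, vertex_index: int | None = None) -> np.ndarray:
    """Bending force: minus the umbrella operator applied twice.

    ``F_rigid = -L(L(v)) = -L(F_elastic)`` — a linear combination of the
    tensile forces over the 2-ring; vanishes wherever every vertex sits at
    its ring centroid.
    """
    lap = elastic_force(mesh)
    forces = -(_ring_mean(mesh, lap) - lap)
    return forces if vertex_index is None else forces[vertex_index]


class _PotentialField:
    """Precomputed gradient volumes of an edge potential for fast sampling."""

    def __init__(self, edge_map: EdgeMap):
        self.edge_map = edge_map
        self.grads = np.gradient(edge_map.data, *edge_map.spacing)
        self.upper_idx = np.array(edge_map.shape, dtype=float) - 1

    def force_at(self, positions: np.ndarray):
        """(-grad P at positions, number of clamped points)."""
        pos = np.atleast_2d(positions)
        idx = self.edge_map.index_coords(pos)
        clamped = int(np.any((idx < 0) | (idx > self.upper_idx), axis=1).sum())
        idx = np.clip(idx, 0, self.upper_idx)
        out = np.empty_like(pos)
        for ax in range(3):
            out[:, ax] = -ndimage.map_coordinates(
                self.grads[ax], idx.T, order=1, mode="nearest"
            )
        return out, clamped

    def potential_at(self, positions: np.ndarray) -> np.ndarray:
        idx = np.clip(self.edge_map.index_coords(np.atleast_2d(positions)),
                      0, self.upper_idx)
        return ndimage.map_coordinates(self.edge_map.data, idx.T, order=1,
                                       mode="nearest")


def external_force(edge_map: EdgeMap, position: np.ndarray) -> np.ndarray:
    """Negative potential gradient, trilinearly interpolated at world position(s).

    Positions outside the edge-map bounds are clamped to the border (the
    evolution trace counts them).
    """
    out, _ = _PotentialField(edge_map).force_at(position)
    return out[0] if np.asarray(position).ndim == 1 else out


# --- sampled self-intersection check -------------------------------------

def _segments_hit_triangles(p, q, a, b, c) -> np.ndarray:
    """Vectorised segment-vs-triangle test for stacked (M, 3) inputs."""
    n = np.cross(b - a, c - a)
    d = q - p
    denom = np.einsum("ij,ij->i", n, d)
    safe = np.abs(denom) > 1e-15
    t = np.where(safe, np.einsum("ij,ij->i", n, a - p) / np.where(safe, denom, 1.0), -1.0)
    hit = safe & (t >= 0.0) & (t <= 1.0)
    x = p + t[:, None] * d
    v0, v1, v2 = c - a, b - a, x - a
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d02 = np.einsum("ij,ij->i", v0, v2)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d12 = np.einsum("ij,ij->i", v1, v2)
    den = d00 * d11 - d01 * d01
    ok = np.abs(den) > 1e-30
    den = np.where(ok, den, 1.0)
    u = (d11 * d02 - d01 * d12) / den
    v = (d00 * d12 - d01 * d02) / den
    return hit & ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12)


def detect_self_intersection(mesh: SurfaceMesh, max_pairs: int = 200000) -> bool:
    """Broad-phase (KD-tree on face centroids) + exact tri-tri narrow phase.

    Face pairs sharing a vertex are skipped; two triangles can only intersect
    if their centroids are within the sum of their circumradii, which bounds
    the broad-phase query radius.  At most ``max_pairs`` candidate pairs are
    tested, so the check is sampled on very tangled meshes.
    """
    from scipy.spatial import cKDTree

    V, F = mesh.vertices, mesh.faces
    tri = V[F]  # (F, 3, 3)
    cen = tri.mean(axis=1)
    rad = np.linalg.norm(tri - cen[:, None, :], axis=2).max()
    pairs = cKDTree(cen).query_pairs(2.0 * rad + 1e-12, output_type="ndarray")
    if len(pairs) == 0:
        return False
    if len(pairs) > max_pairs:
        pairs = pairs[:: len(pairs) // max_pairs + 1]
    fa, fb = F[pairs[:, 0]], F[pairs[:, 1]]
    shared = (fa[:, :, None] == fb[:, None, :]).any(axis=(1, 2))
    pairs = pairs[~shared]
    if len(pairs) == 0:
        return False
    # AABB overlap filter
    lo, hi = tri.min(axis=1), tri.max(axis=1)
    a, b = pairs[:, 0], pairs[:, 1]
    overlap = np.all((hi[a] >= lo[b]) & (hi[b] >= lo[a]), axis=1)
    pairs = pairs[overlap]
    if len(pairs) == 0:
        return False
    t1, t2 = tri[pairs[:, 0]], tri[pairs[:, 1]]
    for src, dst in ((t1, t2), (t2, t1)):
        for i in range(3):
            p, q = src[:, i], src[:, (i + 1) % 3]
            if _segments_hit_triangles(p, q, dst[:, 0], dst[:, 1], dst[:, 2]).any():
                return True
    return False


def evolve(
    mesh: SurfaceMesh,
    edge_map: EdgeMap,
    params: ActiveSurfaceParams | None = None,
) -> tuple[SurfaceMesh, EvolutionTrace]:
    """Evolve the surface on the edge map until force balance.

    Each iteration applies the weighted total force with a step scale
    ``tau = min(tau_max, cfl_fraction * min(spacing) / max|F|)`` so the
    largest vertex displacement never exceeds the CFL bound.  Stops when the
    mean increment drops below ``params.tol`` (converged) or at
    ``params.max_iters``.

    Raises
    ------
    EvolutionError
        If the sampled self-intersection check fires; the trace up to the
        failure is attached to the exception.
    """
    params = params or ActiveSurfaceParams()
    field_ = _PotentialField(edge_map)
    current = mesh.copy()
    trace = EvolutionTrace()
    min_spacing = float(np.min(edge_map.spacing))
    cfl_cap = params.cfl_fraction * min_spacing

    for it in range(1, params.max_iters + 1):
        F = np.zeros_like(current.vertices)
        if params.alpha:
            F += params.alpha * elastic_force(current)
        if params.beta:
            F += params.beta * rigid_force(current)
        clamped = 0
        if params.kappa:
            fext, clamped = field_.force_at(current.vertices)
            F += params.kappa * fext
        fmax = float(np.max(np.linalg.norm(F, axis=1)))
        if fmax == 0:
            trace.converged = True
            trace.iterations = it - 1
            break
        tau = min(params.tau_max, cfl_cap / fmax)
        disp = tau * F
        norms = np.linalg.norm(disp, axis=1)
        current = current.with_vertices(current.vertices + disp)

        trace.mean_increment.append(float(norms.mean()))
        trace.max_increment.append(float(norms.max()))
        trace.energy.append(float(field_.potential_at(current.vertices).mean()))
        trace.out_of_bounds.append(clamped)
        trace.iterations = it

        if (params.self_intersection_every
                and it % params.self_intersection_every == 0
                and detect_self_intersection(current)):
            trace.converged = False
            raise EvolutionError(f"self-intersection detected at iteration {it}",
                                 trace=trace)
        if norms.mean() < params.tol:
            trace.converged = True
            break
    return current, trace
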