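"""Surface-guided nonrigid registration and fusion.

The pipeline is twofold.  First an active surface, triangulated from the
segmentation of the object on one image, is evolved onto the edge map of the
other image, giving a one-to-one correspondence of surface mesh points.
Second, a free-form-deformation control grid wrapping the original surface is
fitted by solving the inverse FFD least-squares problem from those point
displacements, and the dense deformation inside the ROI is interpolated from
the fitted control points.

Registration pushes the model-image ROI intensities through the forward map
into reference space (with trilinear splatting); fusion pulls model
intensities at the deformed positions of the reference ROI back into the
reference frame.

The public surface is statsmodels-like: build a :class:`SurfaceRegistration`
model from the data, call :meth:`~SurfaceRegistration.fit`, and read the
estimates, residuals and diagnostics off the returned
:class:`RegistrationResults` (with a ``summary()`` table); :func:`register`
and :func:`fuse` are thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .active_surface import ActiveSurfaceParams, EvolutionTrace, evolve
from .errors import GeometryError, WarpError
from .ffd import (
    ControlDisplacementSolution,
    FFDGrid,
    build_deformation_matrix,
    displacement_jacobian,
    init_grid,
    interpolate_displacement,
    inverse_solve,
    local_coords,
)
from .mesh import SurfaceMesh, extract_surface
from .metrics import MetricReport, dsc, roi_intensity_std, sigma_reduction
from .volume import BinaryMask, EdgeMap, Volume3D, compute_edge_map, trilinear_sample

__all__ = [
    "SurfaceRegistration",
    "RegistrationResults",
    "Fusion",
    "FusionResults",
    "register",
    "fuse",
    "warp_volume",
]


def _check_frames(a: Volume3D, b: Volume3D) -> None:
    """Require overlapping fields of view in a shared world frame."""
    lo_a, hi_a = a.bounds()
    lo_b, hi_b = b.bounds()
    if np.any(hi_a < lo_b) or np.any(hi_b < lo_a):
        raise GeometryError("volumes do not overlap in world space")


def warp_volume(
    model_vol: Volume3D,
    model_mask: BinaryMask,
    grid: FFDGrid,
    P_star: np.ndarray,
    ref_geometry: Volume3D,
    fill: float | None = None,
) -> tuple[Volume3D, BinaryMask, dict]:
    """Push the model ROI through the FFD onto the reference grid.

    Every ROI voxel centre is mapped forward by the fitted FFD and its
    intensity is splatted trilinearly onto the reference grid; accumulated
    intensity is normalised by accumulated weight, unhit voxels inside the
    deformed ROI are filled from their nearest hit voxel, and voxels outside
    the deformed ROI keep the reference background (or ``fill`` if given).

    Returns (warped volume, warped mask, stats) where stats records the splat
    weight total and the out-of-bounds voxel count.

    Raises
    ------
    WarpError
        Empty ROI, ROI outside the grid support, or a folded deformation
        (non-positive Jacobian determinant at an ROI voxel).
    """
    roi_idx = np.argwhere(model_mask.data > 0)
    if len(roi_idx) == 0:
        raise WarpError("empty ROI")
    x = model_mask.world_coords(roi_idx)
    loc = local_coords(grid, x)
    if np.any((loc < -1e-9) | (loc > 1 + 1e-9)):
        raise WarpError("ROI extends outside the FFD grid support")

    J = displacement_jacobian(grid, P_star, x)
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        raise WarpError(
            f"deformation folds the grid at {int((detJ <= 0).sum())} ROI voxel(s)"
        )

    x_def = interpolate_displacement(grid, P_star, x)
    shape = ref_geometry.shape
    f = (x_def - ref_geometry.origin) / ref_geometry.spacing
    f0 = np.floor(f).astype(np.int64)
    frac = f - f0

    acc_w = np.zeros(shape)
    acc_i = np.zeros(shape)
    intens = model_vol.data[tuple(roi_idx.T)].astype(float)
    out_of_bounds = 0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[:, 0] if dx else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dz else 1 - frac[:, 2])
                )
                tgt = f0 + (dx, dy, dz)
                ok = np.all((tgt >= 0) & (tgt < shape), axis=1)
                if dx == dy == dz == 0:
                    out_of_bounds = int((~np.all(
                        (f0 >= 0) & (f0 + 1 < shape), axis=1)).sum())
                np.add.at(acc_w, tuple(tgt[ok].T), w[ok])
                np.add.at(acc_i, tuple(tgt[ok].T), w[ok] * intens[ok])

    hit = acc_w > 1e-12
    warped_intensity = np.zeros(shape)
    warped_intensity[hit] = acc_i[hit] / acc_w[hit]

    # Deformed ROI: voxels carrying at least half the nominal splat density,
    # morphologically closed and hole-filled to absorb splat shot noise.
    density = model_vol.voxel_volume / ref_geometry.voxel_volume
    mask_raw = acc_w >= 0.45 * density
    mask_closed = ndimage.binary_fill_holes(
        ndimage.binary_closing(mask_raw, ndimage.generate_binary_structure(3, 1))
    )

    # Fill unhit interior voxels from the nearest hit voxel.
    needs_fill = mask_closed & ~hit
    if needs_fill.any():
        _, nearest = ndimage.distance_transform_edt(
            ~hit, sampling=ref_geometry.spacing, return_indices=True
        )
        warped_intensity[needs_fill] = warped_intensity[
            tuple(ix[needs_fill] for ix in nearest)
        ]

    background = np.full(shape, fill, dtype=float) if fill is not None \
        else ref_geometry.data.astype(float).copy()
    out = np.where(mask_closed, warped_intensity, background)
    stats = {
        "splat_weight_total": float(acc_w.sum()),
        "roi_voxels": int(len(roi_idx)),
        "out_of_bounds": out_of_bounds,
        "min_jacobian_det": float(detJ.min()),
    }
    warped_mask = BinaryMask(mask_closed.astype(np.uint8),
                             ref_geometry.spacing, ref_geometry.origin)
    return Volume3D(out, ref_geometry.spacing, ref_geometry.origin), warped_mask, stats


@dataclass
class RegistrationResults:
    """Estimates and diagnostics of a fitted surface-guided registration.

    Attributes
    ----------
    mesh, adapted_mesh : original and adapted surface meshes.
    grid : fitted FFD grid (control points at rest).
    control_points : fitted displaced control points P*.
    residual_rms_mm : inverse-solve residual over surface points.
    warped_volume, warped_mask : model ROI pushed into reference space.
    trace : active-surface evolution trace.
    metrics : :class:`MetricReport` (ROI sigma before/after, reduction, ...).
    """

    model: "SurfaceRegistration"
    mesh: SurfaceMesh
    adapted_mesh: SurfaceMesh
    grid: FFDGrid
    control_points: np.ndarray
    solution: ControlDisplacementSolution
    warped_volume: Volume3D
    warped_mask: BinaryMask
    trace: EvolutionTrace
    metrics: MetricReport
    warp_stats: dict = field(default_factory=dict)

    @property
    def residual_rms_mm(self) -> float:
        return self.solution.residual_rms

    @property
    def control_displacements(self) -> np.ndarray:
        return self.control_points - self.grid.rest_points()

    def displacement_at(self, x) -> np.ndarray:
        """Fitted displacement (mm) of world point(s) inside the grid."""
        x = np.asarray(x, dtype=float)
        return interpolate_displacement(self.grid, self.control_points, x) - x

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        m = self.metrics.to_dict()
        disp = np.linalg.norm(self.control_displacements, axis=1)
        rows = [
            ("surface points", f"{self.mesh.n_vertices}"),
            ("control points", f"{self.grid.n_controls}"),
            ("grid resolution", f"{self.grid.l}x{self.grid.m}x{self.grid.n}"),
            ("solver", f"{self.solution.method} (lambda={self.solution.regularization:.3g})"),
            ("residual RMS [mm]", f"{self.residual_rms_mm:.4f}"),
            ("max control displacement [mm]", f"{disp.max():.3f}"),
            ("evolution iterations", f"{self.trace.iterations}"
                                     f" ({'converged' if self.trace.converged else 'not converged'})"),
        ]
        rows += [(k, f"{v:.4f}" if isinstance(v, float) else str(v))
                 for k, v in sorted(m.items())]
        width = max(len(r[0]) for r in rows) + 2
        lines = ["Surface-guided FFD registration", "=" * 48]
        lines += [f"{k:<{width}}{v}" for k, v in rows]
        return "\n".join(lines)

    def plot_trace(self, ax=None):
        """Plot the evolution increments (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(self.trace.mean_increment, label="mean increment [mm]")
        ax.semilogy(self.trace.max_increment, label="max increment [mm]")
        ax.set_xlabel("iteration")
        ax.set_ylabel("vertex increment [mm]")
        ax.legend()
        return ax

    def save(self, out_dir) -> None:
        """Write all artifacts (mesh, grid, fields, warped images, metrics)."""
        import os

        from .mesh import save_mesh
        from .volume import write_mask, write_volume

        os.makedirs(out_dir, exist_ok=True)
        save_mesh(self.mesh, os.path.join(out_dir, "surface_original.ply"))
        save_mesh(self.adapted_mesh, os.path.join(out_dir, "surface_adapted.ply"))
        grid_out = FFDGrid(self.grid.x0, self.grid.S, self.grid.T, self.grid.U,
                           self.grid.l, self.grid.m, self.grid.n, self.control_points)
        grid_out.to_json(os.path.join(out_dir, "ffd_grid.json"))
        write_volume(self.warped_volume, os.path.join(out_dir, "warped_volume.nii.gz"))
        write_mask(self.warped_mask, os.path.join(out_dir, "warped_mask.nii.gz"))
        self.metrics.to_json(os.path.join(out_dir, "metrics.json"))
        self.trace.to_frame().to_csv(os.path.join(out_dir, "evolution_trace.csv"),
                                     index=False)
        with open(os.path.join(out_dir, "summary.txt"), "w") as fh:
            fh.write(self.summary() + "\n")


class SurfaceRegistration:
    """Surface-guided nonrigid registration model.

    Parameters
    ----------
    model_vol, model_mask : the image carrying the segmentation and its
        binary object mask (shared geometry).
    ref_vol : the image to register onto; must share a world frame with the
        model image (resample beforehand if needed).
    params : :class:`ActiveSurfaceParams` for the surface evolution.
    grid_resolution : FFD subdivisions (l, m, n); the lattice has
        (l+1)(m+1)(n+1) control points.
    grid_margin : fractional inflation of the surface bounding box per side.
    solver, lam : inverse-solve method ("lm" or "pinv") and ridge weight
        (None -> 1e-6 × number of surface points).
    edge_sigma_mm : Gaussian scale of the reference edge map.
    target_vertex_count : optional vertex budget for surface extraction.
    """

    def __init__(
        self,
        model_vol: Volume3D,
        model_mask: BinaryMask,
        ref_vol: Volume3D,
        params: ActiveSurfaceParams | None = None,
        grid_resolution: tuple = (5, 5, 5),
        grid_margin: float = 0.1,
        solver: str = "lm",
        lam: float | None = None,
        edge_sigma_mm: float = 2.0,
        target_vertex_count: int | None = None,
    ):
        if not model_vol.same_geometry(model_mask):
            raise GeometryError("model volume and mask must share geometry")
        _check_frames(model_vol, ref_vol)
        self.model_vol = model_vol
        self.model_mask = model_mask
        self.ref_vol = ref_vol
        self.params = params or ActiveSurfaceParams()
        self.grid_resolution = tuple(grid_resolution)
        self.grid_margin = grid_margin
        self.solver = solver
        self.lam = lam
        self.edge_sigma_mm = edge_sigma_mm
        self.target_vertex_count = target_vertex_count

    # -- pipeline stages (overridable hooks) --------------------------------

    def _extract(self) -> SurfaceMesh:
        return extract_surface(self.model_mask, self.target_vertex_count)

    def _edge_map(self) -> EdgeMap:
        return compute_edge_map(self.ref_vol, self.edge_sigma_mm)

    def fit(self, fill: float | None = None) -> RegistrationResults:
        """Run the twofold pipeline and return the fitted results.

        Stages: extract the surface from the model mask; evolve it on the
        reference edge map; build the deformation matrix on the *original*
        vertices; solve the inverse FFD problem with the adapted vertices as
        targets; warp the model ROI into reference space; compute the metric
        report (ROI sigma of the model-vs-reference difference image before
        and after, within the warped reference ROI).
        """
        mesh = self._extract()
        edge_map = self._edge_map()
        adapted, trace = evolve(mesh, edge_map, self.params)

        lo = mesh.vertices.min(axis=0)
        hi = mesh.vertices.max(axis=0)
        # grid must also support the adapted surface and the ROI interior
        lo = np.minimum(lo, adapted.vertices.min(axis=0))
        hi = np.maximum(hi, adapted.vertices.max(axis=0))
        l, m, n = self.grid_resolution
        grid = init_grid(lo, hi, l, m, n, margin=self.grid_margin)

        B = build_deformation_matrix(grid, mesh.vertices)
        sol = inverse_solve(B, adapted.vertices, P_rest=grid.rest_points(),
                            method=self.solver, lam=self.lam)
        warped_vol, warped_mask, stats = warp_volume(
            self.model_vol, self.model_mask, grid, sol.P_star, self.ref_vol,
            fill=fill,
        )

        diff_before = Volume3D(self.model_vol.data - self.ref_vol.data,
                               self.ref_vol.spacing, self.ref_vol.origin)
        diff_after = Volume3D(warped_vol.data - self.ref_vol.data,
                              self.ref_vol.spacing, self.ref_vol.origin)
        s_before = roi_intensity_std(diff_before, warped_mask)
        s_after = roi_intensity_std(diff_after, warped_mask)
        report = MetricReport(
            roi_sigma_before=s_before,
            roi_sigma_after=s_after,
            sigma_reduction_pct=(
                sigma_reduction(s_before, s_after) if s_before > 0 else None
            ),
            extra={
                "residual_rms_mm": sol.residual_rms,
                "self_dsc": dsc(self.model_mask, warped_mask)
                if self.model_mask.same_geometry(warped_mask) else None,
            },
        )
        return RegistrationResults(
            model=self, mesh=mesh, adapted_mesh=adapted, grid=grid,
            control_points=sol.P_star, solution=sol,
            warped_volume=warped_vol, warped_mask=warped_mask,
            trace=trace, metrics=report, warp_stats=stats,
        )


@dataclass
class FusionResults:
    """Fused overlay volume plus the intermediates that produced it."""

    fused: Volume3D
    mesh: SurfaceMesh
    adapted_mesh: SurfaceMesh
    grid: FFDGrid
    control_points: np.ndarray
    solution: ControlDisplacementSolution
    trace: EvolutionTrace
    out_of_bounds: int = 0

    @property
    def residual_rms_mm(self) -> float:
        return self.solution.residual_rms

    def summary(self) -> str:
        rows = [
            ("surface points", f"{self.mesh.n_vertices}"),
            ("control points", f"{self.grid.n_controls}"),
            ("residual RMS [mm]", f"{self.residual_rms_mm:.4f}"),
            ("out-of-bounds samples", f"{self.out_of_bounds}"),
            ("evolution iterations", f"{self.trace.iterations}"),
        ]
        width = max(len(r[0]) for r in rows) + 2
        return "\n".join(["Surface-guided FFD fusion", "=" * 48]
                         + [f"{k:<{width}}{v}" for k, v in rows])


class Fusion:
    """Reverse-direction intensity transfer (fusion) model.

    The segmentation lives on the *reference* image; its surface is adapted
    onto the *model* image, and model intensity at the deformed position of
    every reference ROI voxel is pulled back (trilinear) into that voxel,
    producing a fused overlay on reference geometry.
    """

    def __init__(
        self,
        ref_vol: Volume3D,
        ref_mask: BinaryMask,
        model_vol: Volume3D,
        params: ActiveSurfaceParams | None = None,
        grid_resolution: tuple = (5, 5, 5),
        grid_margin: float = 0.1,
        solver: str = "lm",
        lam: float | None = None,
        edge_sigma_mm: float = 2.0,
        target_vertex_count: int | None = None,
        background: float = 0.0,
    ):
        if not ref_vol.same_geometry(ref_mask):
            raise GeometryError("reference volume and mask must share geometry")
        _check_frames(ref_vol, model_vol)
        self.ref_vol = ref_vol
        self.ref_mask = ref_mask
        self.model_vol = model_vol
        self.params = params or ActiveSurfaceParams()
        self.grid_resolution = tuple(grid_resolution)
        self.grid_margin = grid_margin
        self.solver = solver
        self.lam = lam
        self.edge_sigma_mm = edge_sigma_mm
        self.target_vertex_count = target_vertex_count
        self.background = background

    def fit(self) -> FusionResults:
        mesh = extract_surface(self.ref_mask, self.target_vertex_count)
        edge_map = compute_edge_map(self.model_vol, self.edge_sigma_mm)
        adapted, trace = evolve(mesh, edge_map, self.params)

        lo = np.minimum(mesh.vertices.min(axis=0), adapted.vertices.min(axis=0))
        hi = np.maximum(mesh.vertices.max(axis=0), adapted.vertices.max(axis=0))
        l, m, n = self.grid_resolution
        grid = init_grid(lo, hi, l, m, n, margin=self.grid_margin)
        B = build_deformation_matrix(grid, mesh.vertices)
        sol = inverse_solve(B, adapted.vertices, P_rest=grid.rest_points(),
                            method=self.solver, lam=self.lam)

        roi_idx = np.argwhere(self.ref_mask.data > 0)
        x = self.ref_mask.world_coords(roi_idx)
        x_def = interpolate_displacement(grid, sol.P_star, x)
        f = (x_def - self.model_vol.origin) / self.model_vol.spacing
        upper = np.array(self.model_vol.shape) - 1
        inside = np.all((f >= 0) & (f <= upper), axis=1)
        vals = np.full(len(x), float(self.background))
        if inside.any():
            vals[inside] = trilinear_sample(self.model_vol.data, f[inside])
        fused = self.ref_vol.data.astype(float).copy()
        fused[tuple(roi_idx.T)] = vals
        return FusionResults(
            fused=Volume3D(fused, self.ref_vol.spacing, self.ref_vol.origin),
            mesh=mesh, adapted_mesh=adapted, grid=grid,
            control_points=sol.P_star, solution=sol, trace=trace,
            out_of_bounds=int((~inside).sum()),
        )


def register(model_vol, model_mask, ref_vol, **kwargs) -> RegistrationResults:
    """Fit a :class:`SurfaceRegistration` in one call."""
    return SurfaceRegistration(model_vol, model_mask, ref_vol, **kwargs).fit()


def fuse(ref_vol, ref_mask, model_vol, **kwargs) -> FusionResults:
    """Fit a :class:`Fusion` in one call."""
    return Fusion(ref_vol, ref_mask, model_vol, **kwargs).fit()
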