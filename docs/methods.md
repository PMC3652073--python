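# Methods

## Model and assumptions

`ffdreg` implements geometry-driven nonrigid registration: the displacement
of an organ is assumed to be dominated by its boundary motion, with a smooth
deformation field inside.  The method therefore (1) finds the boundary
correspondence explicitly with a deformable surface and (2) *interpolates*
the interior deformation from that correspondence alone, through a global
low-dimensional deformation model.  Nothing inside the ROI is matched
directly; consequently internal structures that move tangentially to the
surface, or independently of it, are not recovered (see *Limitations*).

### Active surface

The surface is an explicit closed triangle mesh (not a level set), obtained
by marching cubes at iso-level 0.5 on a Gaussian-smoothed (σ = 1 voxel) copy
of the binary segmentation, oriented outward by the signed-volume test.
Evolution is explicit time stepping on the total force

    F_total = α·F_elastic + β·F_rigid + κ·F_ext

* `F_elastic(i) = Σ_{j∈ring(i)} (v_j − v_i)/|ring(i)|` — the umbrella
  (discrete Laplacian) tensile force; zero when a vertex sits at its ring
  centroid.
* `F_rigid = −L(L(v))` — the umbrella operator applied twice (bi-Laplacian),
  a bending force supported on the 2-ring.  These are the standard discrete
  realisations of stretching and bending for triangle meshes.
* `F_ext = −∇P`, the trilinearly interpolated negative gradient of the
  inverse edge map `P = 1 − ‖∇(G_σ ∗ I)‖ / max‖∇(G_σ ∗ I)‖`.  Image
  gradients are computed by central differences in world millimetres
  (one-sided at borders) because clinical voxels are anisotropic.

The step scale is renormalised each iteration,
`τ = min(τ_max, cfl_fraction · min(spacing) / max_i |F_i|)`, so the largest
vertex displacement never exceeds a fixed fraction of the smallest voxel —
an explicit-scheme stability (CFL-type) bound that is asserted from the
recorded trace in the tests.  Iteration stops when the mean vertex increment
falls below `tol`.

### Inverse free-form deformation

The deformation model is a trivariate *Bernstein* (Bézier) FFD: global
support, infinitely smooth inside the lattice, end-point interpolating at
the eight lattice corners.  The weight of control `(i,j,k)` at a point with
local coordinates `(χ,ψ,ω) ∈ [0,1]³` is
`C(l,i)C(m,j)C(n,k)(1−χ)^{l−i}χ^i(1−ψ)^{m−j}ψ^j(1−ω)^{n−k}ω^k`; rows sum to
one and the basis reproduces affine maps exactly (both properties are
tested to 1e−12 / 1e−9).  Local coordinates come from the triple-product
formulas, which reduce to a 3×3 linear solve for sheared lattices.

Control-point recovery minimises
`‖B·P − S*‖² + λ‖P − P_rest‖²`.  Two solvers are provided:

* `pinv` — direct (regularised) normal equations; minimum-norm least
  squares via `numpy.linalg.lstsq` when λ = 0, with a conditioning warning
  on rank deficiency.
* `lm` — damped least squares (Levenberg–Marquardt): damping ×10 on a
  rejected step, ÷10 on acceptance; convergence when the gradient norm
  drops below 1e−10 or the step below 1e−12.  The objective is quadratic,
  so `lm` agrees with `pinv` to < 1e−4 mm RMS on well-conditioned instances
  (tested); it is retained as the default because it remains well behaved
  when columns of `B` are nearly zero.

λ defaults to `1e−6·N` (N = surface points).  Rationale: Bernstein controls
far from the surface have near-zero columns in `B`; without regularisation
their fitted positions are arbitrary, and the ridge pins them to rest.  The
default is small enough not to bias supported controls (round-trip recovery
RMSE < 1e−6 mm with λ = 0 on full-rank instances).

### Registration and fusion directions

*Registration* pushes every model-ROI voxel centre through the fitted FFD
and splats its intensity trilinearly onto the reference grid (weights
accumulated and normalised; unhit interior voxels filled from their nearest
hit neighbour; the deformed ROI is the set of voxels receiving at least
~half the nominal splat density, morphologically closed).  *Fusion* runs the
surface adaptation in the opposite direction and pulls model intensity at
the deformed position of every reference-ROI voxel (trilinear), writing it
back into the reference frame.  Using push for one direction and pull for
the other avoids ever inverting the deformation numerically.  Folding is
detected by evaluating the FFD Jacobian determinant at ROI voxel centres;
a non-positive determinant is an error, never silently clipped.

## Parameter defaults

| parameter | default | units | why |
|---|---|---|---|
| α (elastic) | 0.3 | – | weak smoothing; keeps the mesh regular without fighting the image force |
| β (rigid) | 0.1 | – | light bending penalty; larger values stiffen the surface against concavities |
| κ (external) | 1.0 | – | image force dominates near edges |
| cfl_fraction | 0.5 | voxel | half-voxel maximum step; explicit-scheme stability |
| tol | 1e−3 | mm | mean-increment convergence threshold |
| edge map σ | 2.0 | mm | wide enough an attraction basin for ~5-voxel initial offsets; blur-induced inward bias ≈ σ²/R stays ≪ 1 voxel for the radii used |
| FFD resolution | 5×5×5 | – | 216 controls; the working range for organ-scale ROIs is 5³–10³ |
| grid margin | 0.1 | fraction/side | keeps the surface strictly inside the support with room to deform |
| λ | 1e−6·N | – | see above |

All defaults are config-overridable (`ActiveSurfaceParams`, model
constructor arguments, CLI flags) and the CLI logs the effective
configuration.

## Synthetic phantoms

The generator emulates a single contrast-enhanced organ in a noisy scan: an
ellipsoid or lobed blob (ellipsoid with a degree-3 angular radius
modulation) of mean intensity 200 inside / 50 outside with additive Gaussian
noise (default sd 5, i.e. contrast-to-noise 30) on a 64³ unit-spacing grid —
values chosen to resemble contrast-enhanced CT of a parenchymal organ at
desk scale.  Ground-truth deformations are genuine member-of-model FFDs:
control displacements sampled from a smooth low-frequency sinusoidal field
(default amplitude 4 mm, antinode at the grid centre, boundary control
layers fixed so the map is continuous with the identity outside the grid);
the deformed images are produced by pull-sampling at the Newton-inverted
map and the exact forward displacement field is returned for every voxel.
The 4 mm amplitude yields mean ROI displacements of 1.5–2.5 voxels —
breathing-scale organ motion scaled to the 64-mm field of view.

What the phantoms do *not* emulate: intensity inhomogeneity and bias
fields, multi-modal intensity relationships, partial-volume slabs from
thick slices, neighbouring structures with competing edges, and
deformations outside the FFD family.  Passing phantom tests therefore
demonstrates correctness of the machinery and the direction of effect of
the quality measures, not clinical accuracy.

## Numerical choices

* Voxel model: node-centred, 0-based; world = origin + index · spacing;
  axis-aligned geometry only (rotated input affines are rejected rather
  than silently dropped).  One stated convention avoids half-voxel drift
  between modules.
* Intensity interpolation is trilinear everywhere.
* Volumes are written as NIfTI-2 (64-bit header geometry) so spacing and
  origin round-trip exactly; MetaImage I/O goes through SimpleITK.
* Dice is implemented as `2|A∩B|/(|A|+|B|)`; a union-denominator variant is
  available behind `printed_variant=True` for comparison but is not Dice
  (it equals twice the Jaccard index and exceeds 1 for nested masks).
* Region variance in the uniformity metric uses squared deviations;
  the normaliser `σ_max² = (g_max−g_min)²/2` is itself squared, so only
  squared deviations are dimensionally consistent.
* The combined averaged contour misalignment pools the two directed means
  weighted by point count (one mean over all nearest-neighbour pairs);
  `weighted=False` gives the unweighted alternative.
* Surface vertex budgets are met by coarsening the marching-cubes sampling
  stride: stride coarsening preserves the closed-manifold guarantees that
  edge-collapse decimation can break, at the cost of only approximate
  budget control.
* Self-intersection checking during evolution is sampled (every 10
  iterations by default): KD-tree broad phase on face centroids, exact
  segment–triangle narrow phase, capped at 2·10⁵ candidate pairs.
* All randomness flows through `numpy.random.default_rng` seeded from a
  single seed; fixed seed ⇒ byte-identical pipeline outputs (tested).
* Degenerate inputs are errors, not warnings: constant volumes (edge map),
  empty or multi-component masks (extraction), folded deformations
  (warping), empty point sets and zero dynamic range (metrics).

## Test problem sizes

The suite and the acceptance script work at 64³ voxels, ~4–8·10³ surface
vertices and 5×5×5 control lattices — the smallest sizes at which every
stage (edge basins wider than the initial offset, overdetermined inverse
problems, subvoxel boundary accuracy) behaves as at clinical scale while a
full run stays in the minutes range on one CPU.  Brute-force metric oracles
run at ≤ 200 points / 10⁴ voxels where exhaustive double loops are exact.

## Known limitations

* Interior deformation is inferred from the boundary only.  Surface points
  can slide tangentially during evolution, so the recovered interior field
  degrades with deformation magnitude even when the boundary fit is
  subvoxel; on phantoms with ~2-voxel mean motion the interior RMSE is
  ~1–2 voxels.  Methods using internal image information will beat this
  where internal displacement matters.
* The ROI-σ quality measure compares the intensity-difference spread before
  and after registration inside the reference ROI.  Its "after" value is
  floor-limited by resampling/splat noise at the boundary contrast, so σ
  reduction is only a meaningful signal when the initial misalignment
  exceeds that floor (≳ 1 voxel mean motion on the phantoms here).
* Bernstein FFDs have global support: every control influences every point,
  so local deformations require higher lattice resolutions than local
  (B-spline) FFDs would; resolutions beyond ~10³ make the inverse problem
  increasingly ill-conditioned for surface-only data.
* Surface evolution does not handle topology changes, and the shrinking
  internal forces require the initialisation to enclose (or sit on) the
  target boundary; an initialisation deep inside the object collapses
  instead of expanding (no balloon force is implemented).
* Evolution convergence (`tol` on the mean increment) does not guarantee a
  global energy minimum; with weak image gradients the surface can settle
  on noise edges.  The trace (per-iteration increments and mean potential)
  is returned for diagnosis.
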