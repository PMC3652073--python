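# ffdreg — surface-guided nonrigid 3D registration and fusion

`ffdreg` registers the region of interest (ROI) of one 3D medical image onto
another by using the *surface* of the segmented object as guidance: organ
motion is assumed to act primarily at the organ boundary, with a smooth
deformation inside.  This suits serial or multimodal imaging of solid organs
(kidney, liver) where a segmentation of the object exists on one image but
dense voxel-wise correspondence is unreliable or too expensive.

## Method

The pipeline is twofold:

1. **Active surface.**  A closed triangle mesh `S`, extracted from the binary
   segmentation on the model image, evolves on an *inverse edge map*
   `P = 1 − ‖∇(G_σ ∗ I)‖ / max‖∇(G_σ ∗ I)‖` of the reference image, in which
   object boundaries are potential minima.  The evolution
   `∂S/∂t = τ(t) (α F_elastic + β F_rigid + κ F_ext)` balances a tensile
   (umbrella, 1-ring) force, a bending (bi-Laplacian, 2-ring) force, and the
   negative potential gradient, with the step scale `τ(t)` renormalised every
   iteration so no vertex moves more than a fixed fraction of a voxel
   (CFL-type bound).  At convergence the mesh sits on the object boundary of
   the reference image, giving a one-to-one displacement of every mesh point.

2. **Inverse free-form deformation.**  A trivariate Bernstein FFD lattice
   with control points `p_ijk = x₀ + (i/l)S + (j/m)T + (k/n)U` wraps the
   original surface.  Stacking the tensor-product Bernstein weight rows of
   the `N` surface points gives the deformation matrix `B`
   (`N × (l+1)(m+1)(n+1)`), with `S = B·P` at rest.  The displaced control
   points `P*` are recovered from the adapted surface `S*` by least squares,

       P* = argmin_P ‖B·P − S*‖² + λ‖P − P_rest‖²,

   solved by pseudoinverse or damped (Levenberg–Marquardt) iteration; the
   small ridge term pins control points without surface support to rest.
   The fitted `P*` interpolates the dense deformation of *every* interior
   point, which is used to warp the model ROI into the reference image
   (registration, forward push + trilinear splat) or to pull model intensity
   back into the reference ROI (fusion).

Evaluation metrics included: Dice similarity coefficient, Hausdorff
distance, averaged contour misalignment, intraregion uniformity, gray-level
contrast, ROI intensity standard deviation (and its percent reduction), and
landmark dislocation.

## Worked example

Register a synthetic ellipsoid phantom onto a smoothly deformed copy of
itself (ground truth known):

```python
import numpy as np
from ffdreg import (PhantomSpec, make_phantom, apply_ground_truth_deformation,
                    SurfaceRegistration, dsc)
from ffdreg.ffd import init_grid
from ffdreg.phantom import smooth_control_displacement

spec = PhantomSpec(shape="ellipsoid", semi_axes_mm=(20, 15, 12),
                   center_mm=(32, 32, 32), noise_sd=5.0, seed=1)
vol, mask = make_phantom(spec)
grid = init_grid(*vol.bounds(), 5, 5, 5, margin=0.0)
disp = smooth_control_displacement(grid, 4.0, seed=2)
deformed_vol, deformed_mask, true_field = apply_ground_truth_deformation(
    vol, mask, grid, disp)

res = SurfaceRegistration(vol, mask, deformed_vol).fit()
print(res.summary())
print("DSC vs true deformed mask:", round(dsc(res.warped_mask, deformed_mask), 4))
```

which prints:

```
Surface-guided FFD registration
================================================
surface points                 4430
control points                 216
grid resolution                5x5x5
solver                         lm (lambda=0.00443)
residual RMS [mm]              0.4039
max control displacement [mm]  28.826
evolution iterations           336 (converged)
residual_rms_mm                0.4039
roi_sigma_after                14.4337
roi_sigma_before               36.8311
self_dsc                       0.9113
sigma_reduction_pct            60.8112

DSC vs true deformed mask: 0.9694
```

The adapted surface fits the deformed boundary to 0.40 mm RMS; the warped
mask overlaps the true deformed mask at Dice 0.97; and the standard
deviation of the model-vs-reference intensity difference inside the ROI
drops from 36.8 to 14.4 (a 60.8 % reduction) — the direction of effect an
accurate registration must show.  `res.warped_volume`, `res.warped_mask`,
`res.control_points` and `res.trace` carry the full intermediates, and
`res.save(out_dir)` writes them to disk.

The same stages are exposed on the command line:

```sh
ffdreg phantom --seed 1 --deform-scale 0.15 --out phantom_out
ffdreg register --model phantom_out/phantom.nii.gz \
    --model-mask phantom_out/phantom_mask.nii.gz \
    --ref phantom_out/phantom_deformed.nii.gz --out register_out
ffdreg evaluate --volume register_out/warped_volume.nii.gz \
    --mask-a register_out/warped_mask.nii.gz \
    --mask-b phantom_out/phantom_deformed_mask.nii.gz --out metrics.json
```

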