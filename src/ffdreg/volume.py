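"""Regular 3D scalar volumes with physical geometry, file I/O and edge maps.

The voxel model is node-centred and 0-based: the world coordinate of voxel
index ``v`` is ``origin + v * spacing`` componentwise, axes are assumed
axis-aligned (no rotation), and array axis order is (x, y, z).  All physical
quantities are in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, FormatError

__all__ = [
    "Volume3D",
    "BinaryMask",
    "EdgeMap",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "compute_edge_map",
    "trilinear_sample",
]


@dataclass
class Volume3D:
    """A scalar intensity volume on a regular anisotropic grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar intensity per voxel.
    spacing : array-like of 3 floats
        Voxel size in mm per axis; strictly positive.
    origin : array-like of 3 floats
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3D, got ndim={self.data.ndim}")
        if any(s < 2 for s in self.data.shape):
            raise FormatError(f"each axis needs >= 2 voxels, got {self.data.shape}")
        if not np.all(self.spacing > 0):
            raise FormatError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self):
        return self.data.shape

    def world_coords(self, indices):
        """World mm of voxel indices (…, 3)."""
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def index_coords(self, world):
        """Fractional voxel indices of world points (…, 3)."""
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def bounds(self):
        """(lower, upper) world mm of the voxel-centre bounding box."""
        upper = self.origin + (np.array(self.shape) - 1) * self.spacing
        return self.origin.copy(), upper

    def same_geometry(self, other: "Volume3D") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


class BinaryMask(Volume3D):
    """A {0,1} segmentation sharing geometry with its parent volume."""

    def __post_init__(self):
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise FormatError("mask values must be in {0, 1}")
        self.data = self.data.astype(np.uint8)
        if not self.data.any():
            raise FormatError("mask has no foreground voxels")

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


@dataclass
class EdgeMap:
    """Edge potential in [0, 1]; object boundaries are local minima.

    ``potential = 1 - |grad(G_sigma * I)| / max |grad(G_sigma * I)|`` so that
    gradient descent on the potential attracts a surface to intensity edges.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    sigma_mm: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self):
        return self.data.shape

    def index_coords(self, world):
        return (np.asarray(world, dtype=float) - self.origin) / self.spacing

    def bounds(self):
        upper = self.origin + (np.array(self.shape) - 1) * self.spacing
        return self.origin.copy(), upper


def compute_edge_map(vol: Volume3D, sigma_mm: float) -> EdgeMap:
    """Inverse edge map of a volume.

    The intensity is smoothed with a Gaussian of physical scale ``sigma_mm``,
    the gradient magnitude is computed by central finite differences in world
    units (one-sided at the borders), and the potential is one minus the
    normalised magnitude, so maximal-gradient loci become potential minima.

    Raises
    ------
    DegenerateInputError
        If the volume is constant (zero gradient everywhere).
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    data = vol.data.astype(float)
    if sigma_mm > 0:
        sigma_vox = sigma_mm / vol.spacing
        data = ndimage.gaussian_filter(data, sigma=sigma_vox)
    gx, gy, gz = np.gradient(data, *vol.spacing)
    gmag = np.sqrt(gx * gx + gy * gy + gz * gz)
    gmax = gmag.max()
    if gmax == 0:
        raise DegenerateInputError("constant volume: edge map undefined")
    return EdgeMap(1.0 - gmag / gmax, vol.spacing, vol.origin, sigma_mm=sigma_mm)


def trilinear_sample(data: np.ndarray, voxel_coords: np.ndarray, mode: str = "nearest") -> np.ndarray:
    """Trilinear interpolation of a 3D array at fractional voxel coordinates (…, 3)."""
    pts = np.atleast_2d(np.asarray(voxel_coords, dtype=float))
    out = ndimage.map_coordinates(data.astype(float), pts.T, order=1, mode=mode)
    return out if np.asarray(voxel_coords).ndim > 1 else out[0]


# ---------------------------------------------------------------------------
# File I/O.  NIfTI goes through nibabel; MetaImage through SimpleITK.  Only
# axis-aligned geometry (spacing + origin) is modelled, which is what the
# package itself writes; rotated input affines are rejected.
# ---------------------------------------------------------------------------

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mha", ".mhd")


def _suffix(path: str) -> str:
    p = str(path).lower()
    if p.endswith(".nii.gz"):
        return ".nii.gz"
    return "." + p.rsplit(".", 1)[-1] if "." in p else ""


def read_volume(path) -> Volume3D:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) scalar volume."""
    suf = _suffix(path)
    if suf in _NIFTI_SUFFIXES:
        import nibabel as nib

        try:
            img = nib.load(str(path))
        except Exception as exc:  # pragma: no cover - nibabel error classes vary
            raise FormatError(f"cannot read {path}: {exc}") from exc
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise FormatError(f"{path}: expected 3D data, got ndim={data.ndim}")
        aff = img.affine
        rot = aff[:3, :3]
        spacing = np.sqrt((rot ** 2).sum(axis=0))
        if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
            raise FormatError(f"{path}: rotated affines are not supported")
        if not np.all(spacing > 0):
            raise FormatError(f"{path}: non-positive spacing {spacing}")
        origin = aff[:3, 3].astype(float)
        return Volume3D(np.asarray(data), spacing, origin)
    if suf in _META_SUFFIXES:
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except Exception as exc:
            raise FormatError(f"cannot read {path}: {exc}") from exc
        if img.GetDimension() != 3:
            raise FormatError(f"{path}: expected 3D data, got {img.GetDimension()}D")
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # zyx -> xyz
        return Volume3D(data, np.array(img.GetSpacing()), np.array(img.GetOrigin()))
    raise FormatError(f"unsupported volume format: {path}")


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume; the format follows the file suffix."""
    suf = _suffix(path)
    if suf in _NIFTI_SUFFIXES:
        import nibabel as nib

        aff = np.eye(4)
        aff[:3, :3] = np.diag(vol.spacing)
        aff[:3, 3] = vol.origin
        # NIfTI-2: 64-bit header geometry, so spacing/origin round-trip exactly
        nib.save(nib.Nifti2Image(np.asarray(vol.data), aff), str(path))
        return
    if suf in _META_SUFFIXES:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in vol.spacing))
        img.SetOrigin(tuple(float(o) for o in vol.origin))
        sitk.WriteImage(img, str(path))
        return
    raise FormatError(f"unsupported volume format: {path}")


def read_mask(path) -> BinaryMask:
    """Read a binary mask (values are thresholded at 0.5)."""
    vol = read_volume(path)
    return BinaryMask((np.asarray(vol.data) > 0.5).astype(np.uint8), vol.spacing, vol.origin)


def write_mask(mask: BinaryMask, path) -> None:
    write_volume(Volume3D(mask.data.astype(np.uint8), mask.spacing, mask.origin), path)
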