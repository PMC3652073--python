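"""Segmentation and registration evaluation metrics.

Discrepancy metrics (Dice overlap, Hausdorff distance, averaged contour
misalignment, landmark dislocation) compare against a reference; goodness
metrics (intraregion uniformity, gray-level contrast, ROI intensity standard
deviation) need no reference.  Contour metrics operate on point sets in
world mm; mask metrics require identical geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import MetricError
from .volume import BinaryMask, Volume3D

__all__ = [
    "ContourPointSet",
    "LandmarkSet",
    "MetricReport",
    "dsc",
    "hausdorff",
    "avg_misalignment",
    "uniformity",
    "gray_contrast",
    "roi_intensity_std",
    "sigma_reduction",
    "landmark_dislocation",
]


def _as_points(pts) -> np.ndarray:
    arr = np.asarray(getattr(pts, "points", pts), dtype=float).reshape(-1, 3)
    if len(arr) == 0:
        raise MetricError("empty contour point set")
    if not np.all(np.isfinite(arr)):
        raise MetricError("non-finite contour coordinates")
    return arr


@dataclass
class ContourPointSet:
    """Contour points in world mm, e.g. surface-mesh vertices."""

    points: np.ndarray

    def __post_init__(self):
        self.points = _as_points(self.points)


@dataclass
class LandmarkSet:
    """Labelled 3D points (label, x, y, z in mm); labels must be unique."""

    labels: list
    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.labels = list(self.labels)
        if len(self.labels) != len(self.points):
            raise MetricError("labels and points disagree in length")
        if len(set(self.labels)) != len(self.labels):
            raise MetricError("landmark labels must be unique")

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        df = pd.read_csv(path)
        return cls(df["label"].tolist(), df[["x", "y", "z"]].to_numpy(float))

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "label": self.labels,
            "x": self.points[:, 0], "y": self.points[:, 1], "z": self.points[:, 2],
        }).to_csv(path, index=False)


def dsc(A: BinaryMask, B: BinaryMask, printed_variant: bool = False) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two masks.

    ``printed_variant=True`` uses |A∪B| in the denominator instead; note that
    variant is not bounded by 1 (it equals 2·Jaccard) and is provided for
    comparison only.
    """
    if not A.same_geometry(B):
        raise MetricError("masks must share geometry")
    a = A.data.astype(bool)
    b = B.data.astype(bool)
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise MetricError("both masks empty: DSC undefined")
    inter = int((a & b).sum())
    if printed_variant:
        union = int((a | b).sum())
        return 2.0 * inter / union
    return 2.0 * inter / (na + nb)


def _directed_dists(kA: np.ndarray, kB: np.ndarray) -> np.ndarray:
    """Nearest-neighbour distance from each point of kA to the set kB."""
    return cKDTree(kB).query(kA)[0]


def hausdorff(kA, kB) -> float:
    """Symmetric Hausdorff distance: max of the two directed maxima (mm)."""
    a, b = _as_points(kA), _as_points(kB)
    return float(max(_directed_dists(a, b).max(), _directed_dists(b, a).max()))


def avg_misalignment(kA, kB, weighted: bool = True) -> float:
    """Combined averaged contour misalignment (mm).

    Mean nearest-point distance evaluated in both directions; by default the
    two directed means are pooled weighted by point count (equivalently, one
    mean over all 2·min pairs), ``weighted=False`` averages the two directed
    means equally.
    """
    a, b = _as_points(kA), _as_points(kB)
    dab = _directed_dists(a, b)
    dba = _directed_dists(b, a)
    if weighted:
        return float((dab.sum() + dba.sum()) / (len(a) + len(b)))
    return float(0.5 * (dab.mean() + dba.mean()))


def uniformity(vol: Volume3D, regions: list[BinaryMask]) -> float:
    """Intraregion uniformity of a segmentation.

    ``U = 1 − Σ_j V_j σ_j² / (V_all σ_max²)`` with σ_j² the population
    intensity variance in region j and ``σ_max² = (g_max − g_min)² / 2`` over
    all segmented voxels.  U <= 1, with equality iff every region is
    internally constant; invariant under affine intensity rescaling.
    """
    if not regions:
        raise MetricError("need at least one region")
    flat = [vol.data[r.data.astype(bool)] for r in regions]
    total = np.concatenate(flat)
    g_rng = total.max() - total.min()
    if g_rng == 0:
        raise MetricError("zero dynamic range over segmented regions")
    sigma_max2 = g_rng ** 2 / 2.0
    v_all = sum(len(f) for f in flat)
    num = sum(len(f) * f.var() for f in flat)
    return float(1.0 - num / (v_all * sigma_max2))


def gray_contrast(vol: Volume3D, region: BinaryMask, background: BinaryMask) -> float:
    """Signal contrast |f0 − fb| / (f0 + fb) of region vs background means."""
    r = region.data.astype(bool)
    b = background.data.astype(bool)
    if not r.any() or not b.any():
        raise MetricError("region and background must be nonempty")
    if (r & b).any():
        raise MetricError("region and background must be disjoint")
    f0 = float(vol.data[r].mean())
    fb = float(vol.data[b].mean())
    if f0 + fb == 0:
        raise MetricError("zero-sum means: contrast undefined")
    return abs(f0 - fb) / (f0 + fb)


def roi_intensity_std(vol: Volume3D, roi: BinaryMask) -> float:
    """Population standard deviation of intensity over the ROI voxels."""
    sel = roi.data.astype(bool)
    if not sel.any():
        raise MetricError("empty ROI")
    return float(vol.data[sel].std())


def sigma_reduction(sigma_before: float, sigma_after: float) -> float:
    """Percent reduction ``100 (σ_before − σ_after) / σ_before``."""
    if sigma_before <= 0:
        raise MetricError("sigma_before must be positive")
    return 100.0 * (sigma_before - sigma_after) / sigma_before


def landmark_dislocation(L1: LandmarkSet, L2: LandmarkSet):
    """Per-landmark Euclidean distance between matched labels.

    Returns ``(per_landmark, mean, sd)`` with per_landmark a dict label ->
    distance mm and sd the population standard deviation.
    """
    if set(L1.labels) != set(L2.labels):
        raise MetricError("landmark label sets differ")
    idx2 = {lab: i for i, lab in enumerate(L2.labels)}
    d = {
        lab: float(np.linalg.norm(L1.points[i] - L2.points[idx2[lab]]))
        for i, lab in enumerate(L1.labels)
    }
    vals = np.array(list(d.values()))
    return d, float(vals.mean()), float(vals.std())


@dataclass
class MetricReport:
    """Collected metric values for one registration/segmentation run."""

    dsc: float | None = None
    hausdorff_mm: float | None = None
    avg_misalignment_mm: float | None = None
    uniformity: float | None = None
    gray_contrast: float | None = None
    roi_sigma_before: float | None = None
    roi_sigma_after: float | None = None
    sigma_reduction_pct: float | None = None
    landmark_mean_mm: float | None = None
    landmark_sd_mm: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        extra = d.pop("extra")
        d.update(extra)
        return {k: v for k, v in d.items() if v is not None}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def to_frame(self) -> pd.DataFrame:
        d = self.to_dict()
        return pd.DataFrame({"metric": list(d), "value": list(d.values())})
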