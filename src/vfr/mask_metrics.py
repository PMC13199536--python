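"""Geometric and volumetric agreement metrics between segmentations.

Implements the four standard mask-comparison metrics — relative volume
difference (RVD), Dice coefficient (DC), mean surface distance (MSD) and
exact (max-form) Hausdorff distance (HD) — plus the binary median smoothing
applied before comparison, the mean cross-sectional area of the vertebral
body, and the three-comparison intra/inter summaries.

Distances are Euclidean distances between boundary voxel centres, in mm;
voxels on the volume border count as boundary.  RVD is asymmetric (second
argument is the reference); DC, MSD and HD are symmetric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .image import SegmentationMask

__all__ = [
    "median_smooth_mask",
    "relative_volume_difference",
    "dice_coefficient",
    "surface_points",
    "mean_surface_distance",
    "hausdorff_distance",
    "cross_sectional_area",
    "pairwise_geometric_summary",
    "GeometricReport",
]

METRIC_NAMES = ("rvd", "dc", "msd_mm", "hd_mm")


def _data(mask) -> np.ndarray:
    return mask.data if isinstance(mask, SegmentationMask) else np.asarray(mask).astype(bool)


def _spacing(mask, spacing):
    if isinstance(mask, SegmentationMask):
        return mask.spacing
    if spacing is None:
        raise ValueError("spacing required for raw arrays")
    s = np.atleast_1d(np.asarray(spacing, float))
    return tuple(s) * 3 if s.size == 1 else tuple(s)


def median_smooth_mask(mask: SegmentationMask,
                       kernel_mm: float = 3.0) -> SegmentationMask:
    """Binary median filter with a cubic window of physical size ``kernel_mm``.

    The window width is ``round(kernel_mm / spacing)`` forced odd.  For a
    binary image the median equals the majority vote, computed here by
    box-counting.  A kernel smaller than one voxel degenerates to the
    identity (with a warning).
    """
    w = int(round(kernel_mm / mask.spacing[0]))
    if w % 2 == 0:
        w += 1
    if w < 3:
        warnings.warn("median kernel smaller than one voxel; mask unchanged")
        return mask.with_data(mask.data.copy())
    counts = ndimage.uniform_filter(mask.data.astype(np.float64), size=w,
                                    mode="reflect") * w ** 3
    return mask.with_data(np.round(counts) > (w ** 3) // 2)


def relative_volume_difference(a, b) -> float:
    """|V(A) - V(B)| / V(B); B is the reference. Returned as a fraction."""
    va = float(_data(a).sum())
    vb = float(_data(b).sum())
    if vb == 0:
        raise ValueError("reference mask B is empty")
    return abs(va - vb) / vb


def dice_coefficient(a, b) -> float:
    """2|A∩B| / (|A|+|B|): 0 = disjoint, 1 = identical."""
    da, db = _data(a), _data(b)
    denom = int(da.sum()) + int(db.sum())
    if denom == 0:
        raise ValueError("both masks empty: Dice undefined")
    return 2.0 * int((da & db).sum()) / denom


def surface_points(mask, spacing=None) -> np.ndarray:
    """Centres (mm) of mask voxels with a face-adjacent background neighbour.

    Voxels touching the volume border are boundary by definition.
    """
    data = _data(mask)
    if not data.any():
        raise ValueError("empty mask has no surface")
    sp = _spacing(mask, spacing)
    struct = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(data, structure=struct, border_value=0)
    surf = data & ~interior
    idx = np.argwhere(surf)
    return (idx + 0.5) * np.asarray(sp)


def _directed_nn(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Nearest-neighbour distances from each point of A to the set B."""
    d, _ = cKDTree(pb).query(pa, k=1)
    return d


def mean_surface_distance(a, b, spacing=None) -> float:
    """Symmetric mean of the two directed mean nearest-surface distances, mm."""
    pa = surface_points(a, spacing)
    pb = surface_points(b, spacing)
    return 0.5 * (float(_directed_nn(pa, pb).mean())
                  + float(_directed_nn(pb, pa).mean()))


def hausdorff_distance(a, b, spacing=None) -> float:
    """Exact Hausdorff distance between boundary voxel centres, mm."""
    pa = surface_points(a, spacing)
    pb = surface_points(b, spacing)
    return max(float(_directed_nn(pa, pb).max()),
               float(_directed_nn(pb, pa).max()))


def cross_sectional_area(mask: SegmentationMask,
                         endplate_fraction: float = 0.10) -> float:
    """Mean transverse cross-sectional area of the body, mm².

    Averages voxel-count area over the transverse (z) slices that contain
    mask, after dropping an ``endplate_fraction`` band of slices at each
    end (the endplates).  Expects a vertebral-body-scope mask.
    """
    data = _data(mask)
    occupied = np.flatnonzero(data.any(axis=(0, 1)))
    if occupied.size == 0:
        raise ValueError("empty mask")
    n = occupied.size
    drop = int(np.floor(endplate_fraction * n))
    usable = occupied[drop:n - drop] if drop > 0 else occupied
    if usable.size < 3:
        raise ValueError("fewer than 3 usable slices for CSA")
    pix_area = mask.spacing[0] * mask.spacing[1]
    counts = data[:, :, usable].sum(axis=(0, 1))
    return float(counts.mean()) * pix_area


@dataclass
class GeometricReport:
    """Three-comparison agreement summary for one vertebra and mode."""

    mode: str                     # "intra" | "inter"
    scope: str                    # "body" | "whole"
    per_pair: pd.DataFrame        # one row per comparison
    mean: dict[str, float]
    sd: dict[str, float]
    voxel_mm: float

    def as_row(self) -> dict:
        row = {"mode": self.mode, "scope": self.scope}
        for m in METRIC_NAMES:
            row[f"{m}_mean"] = self.mean[m]
            row[f"{m}_sd"] = self.sd[m]
        # distance metrics additionally in voxel units
        for m in ("msd_mm", "hd_mm"):
            row[m.replace("_mm", "_vox") + "_mean"] = self.mean[m] / self.voxel_mm
            row[m.replace("_mm", "_vox") + "_sd"] = self.sd[m] / self.voxel_mm
        return row


def pairwise_geometric_summary(masks, mode: str,
                               smooth: bool = True,
                               kernel_mm: float = 3.0) -> GeometricReport:
    """All four metrics over the three unordered pairs of three masks.

    Pairs are (1,2), (1,3), (2,3) in input order; the *second* member of
    each pair is the RVD reference.  Masks are median-smoothed first by
    default, matching the pipeline order (disable with ``smooth=False``).
    """
    masks = list(masks)
    if len(masks) != 3:
        raise ValueError(f"{mode} summary needs exactly 3 masks, got {len(masks)}")
    if mode not in ("intra", "inter"):
        raise ValueError("mode must be 'intra' or 'inter'")
    if smooth:
        masks = [median_smooth_mask(m, kernel_mm) for m in masks]

    rows = []
    for i, j in combinations(range(3), 2):
        a, b = masks[i], masks[j]
        rows.append({
            "pair": f"{i + 1}v{j + 1}",
            "rvd": relative_volume_difference(a, b),
            "dc": dice_coefficient(a, b),
            "msd_mm": mean_surface_distance(a, b),
            "hd_mm": hausdorff_distance(a, b),
        })
    table = pd.DataFrame(rows).set_index("pair")
    mean = {m: float(table[m].mean()) for m in METRIC_NAMES}
    sd = {m: float(table[m].std(ddof=1)) for m in METRIC_NAMES}
    return GeometricReport(mode=mode, scope=masks[0].scope, per_pair=table,
                           mean=mean, sd=sd, voxel_mm=masks[0].spacing[0])
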