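"""3D FISH geometry: centroids, radial and pairwise distances, volumes.

Confocal stacks of structurally preserved nuclei give voxelized nucleus and
chromosome-territory masks.  This module measures the geometric (unweighted)
centre of each mask in physical μm — honouring anisotropic voxels, e.g.
0.3 μm optical sections with finer xy sampling — the Euclidean distance from
each territory centre to the nuclear centre, frequency distributions of
those distances, all pairwise distances between two territory groups within
each nucleus (with min/Q1/median/Q3/max summaries for box plots), and region
volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import NucleusMask

logger = logging.getLogger(__name__)

__all__ = [
    "CentroidRecord",
    "DistanceSet",
    "geometric_center",
    "center_distance",
    "distance_frequency",
    "pairwise_ct_distances",
    "region_volume",
    "radial_fraction",
]


@dataclass
class CentroidRecord:
    """Geometric centre of one mask, in μm, with its provenance."""

    nucleus_id: int
    object_label: str
    center: tuple[float, ...]  # (x, y) or (x, y, z) in μm
    voxel_size: tuple[float, ...]  # sampling in the same axis order


def geometric_center(
    mask: NucleusMask, object_label: str = "nucleus", intensity: np.ndarray | None = None
) -> CentroidRecord:
    """Unweighted centroid of the member voxel centres, scaled to μm.

    The voxel at index ``(z, y, x)`` occupies a box whose centre is at
    ``((x+0.5)*px, (y+0.5)*px, (z+0.5)*z_step)`` μm; the centroid averages
    those centres.  Pass ``intensity`` for an intensity-weighted variant.
    """
    if mask.size_px == 0:
        raise ValueError("empty mask has no centroid")
    coords = np.argwhere(mask.mask).astype(float) + 0.5  # array order: (z,)y,x
    if intensity is not None:
        w = np.asarray(intensity, dtype=float)[mask.mask]
        if w.sum() <= 0:
            raise ValueError("non-positive total intensity weight")
        mean_idx = (coords * w[:, None]).sum(axis=0) / w.sum()
    else:
        mean_idx = coords.mean(axis=0)
    spacing = np.asarray(mask.spacing())  # (z,)y,x
    center_axis_order = mean_idx * spacing
    center_xyz = tuple(center_axis_order[::-1].tolist())  # -> x, y(, z)
    return CentroidRecord(
        nucleus_id=mask.label,
        object_label=object_label,
        center=center_xyz,
        voxel_size=tuple(spacing[::-1].tolist()),
    )


def center_distance(a: CentroidRecord, b: CentroidRecord) -> float:
    """Euclidean distance in μm between two centroids of the same frame."""
    if len(a.center) != len(b.center):
        raise ValueError("centroids have different dimensionality")
    if a.voxel_size != b.voxel_size:
        raise ValueError("centroids come from frames with different sampling")
    return float(np.linalg.norm(np.subtract(a.center, b.center)))


def distance_frequency(distances, bin_width: float = 1.0) -> pd.DataFrame:
    """Histogram distances on half-open bins [i*w, (i+1)*w).

    Returns a DataFrame with bin edges, counts and relative frequencies
    (summing to 1).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise ValueError("no distances to bin")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    n_bins = int(np.floor(d.max() / bin_width)) + 1
    idx = np.floor(d / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    left = np.arange(n_bins) * bin_width
    return pd.DataFrame(
        {
            "bin_left": left,
            "bin_right": left + bin_width,
            "count": counts,
            "rel_freq": counts / d.size,
        }
    )


@dataclass
class DistanceSet:
    """Pooled pairwise distances for one territory pair, with box summary."""

    pair: str
    distances: tuple[float, ...]
    n_nuclei: int

    @property
    def summary(self) -> dict[str, float]:
        """min, Q1, median, Q3, max (quartiles by linear interpolation)."""
        d = np.asarray(self.distances)
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        return {
            "min": float(d.min()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "max": float(d.max()),
        }


def pairwise_ct_distances(
    per_nucleus: list[tuple[list[CentroidRecord], list[CentroidRecord]]],
    pair: str = "A-B",
    min_nuclei: int = 1,
) -> DistanceSet:
    """All A×B centroid distances within each nucleus, pooled across nuclei.

    ``per_nucleus`` holds, for each nucleus, the centroid records of the two
    territory groups (e.g. a relocating and a static chromosome, both with
    two homologs).  Nuclei missing either group are skipped with a log
    entry.  Raises if fewer than ``min_nuclei`` nuclei contribute.
    """
    distances: list[float] = []
    used = 0
    for i, (group_a, group_b) in enumerate(per_nucleus):
        if not group_a or not group_b:
            logger.info("nucleus %d lacks one territory group; skipped", i)
            continue
        used += 1
        for ca in group_a:
            for cb in group_b:
                distances.append(center_distance(ca, cb))
    if used < min_nuclei:
        raise ValueError(f"only {used} nuclei contributed; need >= {min_nuclei}")
    return DistanceSet(pair=pair, distances=tuple(distances), n_nuclei=used)


def radial_fraction(nucleus: NucleusMask, point_um: tuple[float, ...]) -> float:
    """Radial fraction of a point: centre offset over boundary distance.

    The fraction is the distance from the nuclear centre to ``point_um``
    (x, y[, z] in μm) divided by the distance from the centre to the mask
    boundary along the same ray (found by marching the ray at quarter-voxel
    steps).  0 is the exact centre, 1 the boundary — the same coordinate the
    synthetic generator uses for territory placement, so a recovered
    territory centroid maps straight back onto its ground-truth ρ.
    """
    center = np.asarray(geometric_center(nucleus).center)
    v = np.asarray(point_um, dtype=float) - center
    dist = float(np.linalg.norm(v))
    if dist == 0.0:
        return 0.0
    u = v / dist
    spacing_xyz = np.asarray(nucleus.spacing())[::-1]  # x, y(, z)
    step = 0.25 * spacing_xyz.min()
    shape = nucleus.mask.shape
    t = 0.0
    boundary = None
    while True:
        t += step
        pos = center + t * u
        idx = np.floor(pos / spacing_xyz).astype(int)[::-1]  # -> (z,)y,x
        if np.any(idx < 0) or np.any(idx >= shape) or not nucleus.mask[tuple(idx)]:
            boundary = t
            break
        if t > 100 * max(shape) * step * 4:  # safety; never hit for sane masks
            raise RuntimeError("ray marching failed to leave the mask")
    return dist / boundary


def region_volume(mask: NucleusMask) -> float:
    """Mask volume in μm³ (3D) — voxel count times voxel volume."""
    if mask.size_px == 0:
        raise ValueError("empty mask has no volume")
    if mask.ndim != 3:
        raise ValueError("region_volume expects a 3D mask; use size_um for areas")
    return mask.size_um
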