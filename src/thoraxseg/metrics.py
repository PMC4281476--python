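"""Segmentation evaluation: volume overlap and symmetric surface distances.

Two segmentations A (automatic) and M (manual/reference) are compared with

* the volume overlap ratio ``VOR = 100 * |A ∩ M| / |A ∪ M]`` (the Jaccard
  index expressed as a percentage), and
* symmetric surface distances.  A surface voxel is a structure voxel with at
  least one of its 18 neighbours (faces + edges) outside the structure; the
  volume boundary counts as outside.  For each surface voxel of one
  structure the Euclidean distance (mm, anisotropic spacing, voxel centres)
  to the nearest surface voxel of the other structure is taken, and the
  average (ASD), root-mean-square (RMSD) and maximum (MSD) over both
  directed sets are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as ndi

from ._util import STRUCT_3D_18
from .volume import check_congruent

__all__ = [
    "MetricReport",
    "volume_overlap_ratio",
    "surface_voxels",
    "symmetric_surface_distances",
    "compare_masks",
]


@dataclass
class MetricReport:
    """Per-structure comparison record."""

    structure: str
    vor_pct: float
    asd_mm: float
    rmsd_mm: float
    msd_mm: float

    def as_dict(self) -> dict:
        return asdict(self)


def volume_overlap_ratio(a: np.ndarray, m: np.ndarray) -> float:
    """Volume overlap ratio (%) between two congruent boolean masks.

    The voxel volume factor cancels between numerator and denominator, so
    only voxel counts enter.  Raises ``ValueError`` if both masks are empty
    (the ratio is undefined).
    """
    a = np.asarray(a, dtype=bool)
    m = np.asarray(m, dtype=bool)
    check_congruent(a, m)
    union = np.count_nonzero(a | m)
    if union == 0:
        raise ValueError("VOR undefined: both masks are empty")
    inter = np.count_nonzero(a & m)
    return 100.0 * inter / union


def surface_voxels(s: np.ndarray) -> np.ndarray:
    """Boolean mask of surface voxels of ``s`` (18-neighbourhood).

    A voxel of ``s`` is a surface voxel if at least one of its 18
    neighbours is outside ``s``; neighbours beyond the volume border count
    as outside (``border_value=0`` in the erosion).
    """
    s = np.asarray(s, dtype=bool)
    if s.ndim != 3:
        raise ValueError("surface_voxels expects a 3D mask")
    interior = ndi.binary_erosion(s, structure=STRUCT_3D_18, border_value=0)
    return s & ~interior


def symmetric_surface_distances(
    a: np.ndarray,
    m: np.ndarray,
    spacing: tuple[float, float, float],
) -> tuple[float, float, float]:
    """(ASD, RMSD, MSD) in mm between two congruent non-empty masks.

    ``spacing`` is the per-axis voxel step in array axis order
    ``(slice, row, col)``.  Distances are computed with a Euclidean
    distance transform of each surface set, which honours anisotropic
    spacing exactly (voxel centres).
    """
    a = np.asarray(a, dtype=bool)
    m = np.asarray(m, dtype=bool)
    check_congruent(a, m)
    surf_a = surface_voxels(a)
    surf_m = surface_voxels(m)
    n_a = int(np.count_nonzero(surf_a))
    n_m = int(np.count_nonzero(surf_m))
    if n_a == 0 or n_m == 0:
        raise ValueError("surface distances undefined: a mask has no surface voxels")

    # distance from every voxel to the nearest surface voxel of the other set
    dt_to_m = ndi.distance_transform_edt(~surf_m, sampling=spacing)
    dt_to_a = ndi.distance_transform_edt(~surf_a, sampling=spacing)
    d_a = dt_to_m[surf_a]  # directed A -> M
    d_m = dt_to_a[surf_m]  # directed M -> A

    total = n_a + n_m
    asd = (d_a.sum() + d_m.sum()) / total
    rmsd = float(np.sqrt((np.square(d_a).sum() + np.square(d_m).sum()) / total))
    msd = float(max(d_a.max(), d_m.max()))
    return float(asd), rmsd, float(msd)


def compare_masks(
    a: np.ndarray,
    m: np.ndarray,
    spacing: tuple[float, float, float],
    structure: str = "",
) -> MetricReport:
    """Full metric report (VOR + surface distances) for one structure."""
    vor = volume_overlap_ratio(a, m)
    asd, rmsd, msd = symmetric_surface_distances(a, m, spacing)
    return MetricReport(structure=structure, vor_pct=vor, asd_mm=asd, rmsd_mm=rmsd, msd_mm=msd)
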