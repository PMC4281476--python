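"""Trachea / main-bronchi segmentation.

The trachea is found on the most superior slices as the air-filled
(HU < -900) component closest to the body centre, and the airway lumen is
grown from its mean pixel location by 3D region growing with an adaptive
threshold:

* the threshold starts at -900 HU and is raised by an increment that starts
  at 64 HU;
* after each step, if the grown volume is at least twice the previously
  accepted volume the growth is considered to have leaked ("exploded")
  through the bronchial wall into the parenchyma; the step is revoked and
  the increment is halved;
* growing terminates when the increment has reached 1 HU and leakage is
  detected, returning the last accepted (non-leaking) lumen.

The airway wall is then included by a per-slice morphological dilation with
a 3x3 disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from ._util import DISK3, STRUCT_3D_26
from .body import BodyMask
from .volume import CTVolume

log = logging.getLogger(__name__)

__all__ = [
    "SeedNotFoundError",
    "GrowthStep",
    "RegionGrowthResult",
    "AirwayMask",
    "detect_trachea_seed",
    "adaptive_region_grow",
    "finalize_airway",
]


class SeedNotFoundError(RuntimeError):
    """No air-filled candidate component found in the top slices."""


def detect_trachea_seed(
    ct: CTVolume,
    body: BodyMask,
    n_top_slices: int = 5,
    air_hu: float = -900.0,
    min_area_mm2: float = 20.0,
) -> tuple[int, int, int]:
    """Locate the trachea seed in the most superior slices.

    Air-filled voxels (HU < ``air_hu``) inside the body on the first
    ``n_top_slices`` slices are grouped into 3D connected components
    (26-connectivity).  Components smaller than ``min_area_mm2`` of
    in-plane-equivalent area are treated as noise.  Among the rest, the
    component whose in-plane centroid is closest to the body centroid is
    the trachea (ties broken by larger size), and the rounded mean pixel
    location of its voxels is the seed.
    """
    n_top = min(int(n_top_slices), ct.n_slices)
    slab_air = (ct.data[:n_top] < air_hu) & body.mask[:n_top]
    if not body.mask[:n_top].any():
        raise SeedNotFoundError("body mask empty in the top slices")
    labels, n = ndi.label(slab_air, structure=STRUCT_3D_26)
    if n == 0:
        raise SeedNotFoundError("no air-filled voxel below %.0f HU in the top slices" % air_hu)

    brows, bcols = np.nonzero(body.mask[:n_top].any(axis=0))
    body_centroid = np.array([brows.mean(), bcols.mean()])

    # minimum voxel count: an average in-plane footprint of min_area_mm2
    min_voxels = max(1, int(round(min_area_mm2 / ct.pixel_area_mm2)))
    best = None  # (distance, -size, seed)
    for i in range(1, n + 1):
        zz, rr, cc = np.nonzero(labels == i)
        size = zz.size
        if size < min_voxels:
            continue
        centroid = np.array([rr.mean(), cc.mean()])
        dist = float(np.linalg.norm(centroid - body_centroid))
        key = (dist, -size)
        if best is None or key < best[0]:
            seed = (int(round(zz.mean())), int(round(rr.mean())), int(round(cc.mean())))
            if not slab_air[seed]:
                # mean location can fall outside a non-convex component;
                # snap to the nearest component voxel
                d2 = (zz - seed[0]) ** 2 + (rr - seed[1]) ** 2 + (cc - seed[2]) ** 2
                j = int(np.argmin(d2))
                seed = (int(zz[j]), int(rr[j]), int(cc[j]))
            best = (key, seed)
    if best is None:
        raise SeedNotFoundError("all air-filled components below the minimum area")
    return best[1]


@dataclass
class GrowthStep:
    """One attempted growth step of the adaptive region growing."""

    threshold: int
    increment: int
    volume: int
    accepted: bool
    leaked: bool


@dataclass
class RegionGrowthResult:
    """Final lumen mask plus the full threshold/volume trace."""

    mask: np.ndarray
    trace: list[GrowthStep] = field(default_factory=list)

    @property
    def accepted_thresholds(self) -> list[int]:
        return [s.threshold for s in self.trace if s.accepted]

    @property
    def increments(self) -> list[int]:
        return [s.increment for s in self.trace]


def _flood(ct_data: np.ndarray, threshold: int, seed: tuple[int, int, int]) -> np.ndarray:
    """26-connected component of {HU < threshold} containing the seed."""
    labels, n = ndi.label(ct_data < threshold, structure=STRUCT_3D_26)
    lab = labels[seed]
    if lab == 0:
        return np.zeros(ct_data.shape, dtype=bool)
    return labels == lab

def adaptive_region_grow(
    ct: CTVolume,
    seed: tuple[int, int, int],
    initial_threshold: int = -900,
    initial_increment: int = 64,
    max_threshold: int = 0,
) -> RegionGrowthResult:
    """Grow the airway lumen with an adaptive threshold and explosion control.

    ``max_threshold`` is a safety cap for degenerate inputs in which no
    leakage ever occurs (e.g. a volume that is entirely air); anatomically
    the doubling rule terminates the growth well below it.
    """
    for i, bound in enumerate(ct.shape):
        if not (0 <= seed[i] < bound):
            raise IndexError(f"seed {seed} outside volume of shape {ct.shape}")
    if ct.data[tuple(seed)] >= initial_threshold:
        raise ValueError(
            f"seed HU {ct.data[tuple(seed)]:.0f} not below the initial threshold "
            f"{initial_threshold} HU"
        )

    threshold = int(initial_threshold)
    increment = int(initial_increment)
    mask = _flood(ct.data, threshold, seed)
    prev_volume = int(mask.sum())
    trace = [GrowthStep(threshold, increment, prev_volume, accepted=True, leaked=False)]

    while True:
        cand_threshold = threshold + increment
        cand = _flood(ct.data, cand_threshold, seed)
        cand_volume = int(cand.sum())
        leaked = cand_volume >= 2 * prev_volume
        trace.append(
            GrowthStep(cand_threshold, increment, cand_volume, accepted=not leaked, leaked=leaked)
        )
        if leaked:
            if increment == 1:
                break  # increment exhausted and leakage detected: stop
            increment //= 2
        else:
            threshold = cand_threshold
            mask = cand
            prev_volume = cand_volume
            if threshold >= max_threshold:
                log.warning(
                    "region growing reached the %d HU safety cap without leakage", max_threshold
                )
                break
    return RegionGrowthResult(mask=mask, trace=trace)


@dataclass
class AirwayMask:
    """Airway lumen plus wall (after dilation)."""

    mask: np.ndarray
    lumen: np.ndarray


def finalize_airway(lumen: np.ndarray) -> AirwayMask:
    """Include the airway wall by per-slice dilation with a 3x3 disk."""
    lumen = np.asarray(lumen, dtype=bool)
    out = np.zeros_like(lumen)
    for k in range(lumen.shape[0]):
        if lumen[k].any():
            out[k] = ndi.binary_dilation(lumen[k], structure=DISK3)
    return AirwayMask(mask=out, lumen=lumen)
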