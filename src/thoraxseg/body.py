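"""Body-region segmentation.

The patient body is extracted slice by slice: voxels with HU in the
soft-tissue window [-175, 750] are thresholded, interior holes (lungs,
airways, bowel gas) are filled per slice, and only 2D connected components
with area strictly greater than 800 mm^2 are accepted.  More than one
component may survive (e.g. the arms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from ._util import fill_holes_2d, label_2d
from .volume import CTVolume

log = logging.getLogger(__name__)

__all__ = ["BodyMask", "segment_body"]


@dataclass
class RegionStats:
    """Per-component statistics of one 2D region."""

    slice_index: int
    area_mm2: float
    centroid: tuple[float, float]  # (row, col)
    bbox: tuple[int, int, int, int]  # (top, bottom, left, right), inclusive


@dataclass
class BodyMask:
    """Per-slice body masks plus per-component statistics."""

    mask: np.ndarray  # 3D boolean, (slice, row, col)
    regions: list[RegionStats] = field(default_factory=list)

    @property
    def shape(self):
        return self.mask.shape

    def centroid_2d(self, slice_index: int) -> tuple[float, float] | None:
        """(row, col) centroid of the body on one slice, or None if empty."""
        sl = self.mask[slice_index]
        if not sl.any():
            return None
        rows, cols = np.nonzero(sl)
        return float(rows.mean()), float(cols.mean())


def segment_body(
    ct: CTVolume,
    hu_low: float = -175.0,
    hu_high: float = 750.0,
    min_area_mm2: float = 800.0,
) -> BodyMask:
    """Segment the body region of every slice.

    Thresholding uses the closed HU window ``[hu_low, hu_high]``; holes are
    filled in 2D; components with area <= ``min_area_mm2`` are discarded
    (strict "greater than" acceptance).
    """
    pixel_area = ct.pixel_area_mm2
    fg = (ct.data >= hu_low) & (ct.data <= hu_high)
    out = np.zeros(ct.shape, dtype=bool)
    regions: list[RegionStats] = []
    for k in range(ct.n_slices):
        filled = fill_holes_2d(fg[k])
        labels, n = label_2d(filled, connectivity=8)
        if n == 0:
            log.warning("slice %d: no body component survives thresholding", k)
            continue
        kept = np.zeros_like(filled)
        objects = ndi.find_objects(labels)
        for i, slc in enumerate(objects, start=1):
            comp = labels[slc] == i
            area = comp.sum() * pixel_area
            if area > min_area_mm2:
                kept[slc] |= comp
                rr, cc = np.nonzero(comp)
                regions.append(
                    RegionStats(
                        slice_index=k,
                        area_mm2=float(area),
                        centroid=(
                            float(rr.mean() + slc[0].start),
                            float(cc.mean() + slc[1].start),
                        ),
                        bbox=(
                            slc[0].start,
                            slc[0].stop - 1,
                            slc[1].start,
                            slc[1].stop - 1,
                        ),
                    )
                )
        if not kept.any():
            log.warning("slice %d: all body components below %.0f mm^2", k, min_area_mm2)
        out[k] = kept
    return BodyMask(mask=out, regions=regions)
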