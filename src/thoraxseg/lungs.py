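"""Lung-field segmentation.

Pipeline order: rough thresholding inside the body (-300 HU), removal of
the trachea/main bronchi, per-slice hole filling and double closing, 3D
correction against bowel gas, anterior/posterior junction-line separation
of fused lungs, and finally inclusion of excluded pathological areas
(tumours and juxtapleural nodules lost by thresholding) as the
intersection of slice-interpolated and neighbourhood-propagated lungs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from ._util import DISK3, STRUCT_3D_26, STRUCT_3D_6, fill_holes_2d, label_2d
from .airway import AirwayMask
from .body import BodyMask
from .volume import CTVolume, check_congruent

log = logging.getLogger(__name__)

__all__ = [
    "LungMask",
    "JunctionROI",
    "rough_lung_fields",
    "remove_airway_fill_close",
    "correct_lung_fields",
    "junction_roi",
    "separate_lungs",
    "interpolate_lungs",
    "propagate_lung",
    "include_pathology",
]


@dataclass
class LungMask:
    """Left/right lung masks.  ``left`` is the patient's left lung, which
    appears on the image right (radiological convention)."""

    left: np.ndarray
    right: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return self.left | self.right


@dataclass(frozen=True)
class JunctionROI:
    """Region of interest for the junction-line search on one slice."""

    left: int
    right: int
    top: int
    bottom: int


def rough_lung_fields(ct: CTVolume, body: BodyMask, threshold_hu: float = -300.0) -> np.ndarray:
    """Voxels inside the body with HU below the lung threshold."""
    return (ct.data < threshold_hu) & body.mask


def remove_airway_fill_close(rough: np.ndarray, airway: AirwayMask) -> np.ndarray:
    """Remove the airway, fill holes and close (twice) per slice."""
    check_congruent(rough, airway.mask)
    out = rough & ~airway.mask
    for k in range(out.shape[0]):
        sl = fill_holes_2d(out[k])
        sl = ndi.binary_closing(sl, structure=DISK3, border_value=0)
        sl = ndi.binary_closing(sl, structure=DISK3, border_value=0)
        out[k] = sl
    return out


def correct_lung_fields(
    lungs: np.ndarray,
    min_area_mm2: float = 200.0,
    pixel_area_mm2: float = 1.0,
    central_slice: int | None = None,
) -> np.ndarray:
    """3D correction of the rough lung fields.

    Removes per-slice regions smaller than ``min_area_mm2`` and keeps only
    voxels 3D-connected (26-connectivity) to lung regions of the central
    slice, which removes bowel gas appearing in caudal slices.  Never adds
    voxels.
    """
    lungs = np.asarray(lungs, dtype=bool)
    out = np.zeros_like(lungs)
    for k in range(lungs.shape[0]):
        labels, n = label_2d(lungs[k], connectivity=8)
        if n == 0:
            continue
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts * pixel_area_mm2 >= min_area_mm2)
        keep = keep[keep > 0]
        out[k] = np.isin(labels, keep)

    if central_slice is None:
        central_slice = lungs.shape[0] // 2
    if not out[central_slice].any():
        log.warning("central slice %d has no lung region; 3D correction skipped", central_slice)
        return out
    labels3, n3 = ndi.label(out, structure=STRUCT_3D_26)
    seeds = np.unique(labels3[central_slice][out[central_slice]])
    seeds = seeds[seeds > 0]
    return np.isin(labels3, seeds)


def junction_roi(bbox: tuple[int, int, int, int]) -> JunctionROI:
    """ROI for the junction-line search from a lung bounding box.

    ``bbox`` is (top, bottom, left, right).  The ROI covers the middle
    third of the columns and the upper half of the rows; fractional
    divisions floor to integer pixel indices.
    """
    top, bottom, left, right = bbox
    width = right - left
    return JunctionROI(
        left=left + width // 3,
        right=left + (2 * width) // 3,
        top=top,
        bottom=top + (bottom - top) // 2,
    )


def _walk_junction(
    hu_slice: np.ndarray,
    lung_slice: np.ndarray,
    start: tuple[int, int],
    direction: int,
    row_limit: int,
    max_steps: int,
) -> int:
    """Walk a junction line from ``start`` relabelling lung pixels as
    non-lung (in place), moving one row per step in ``direction`` (-1 =
    anterior/up, +1 = posterior/down) toward the neighbour of maximum HU.
    Ties prefer the centre column, then the left.  Returns the number of
    relabelled pixels."""
    n_rows, n_cols = hu_slice.shape
    r, c = start
    removed = 0
    for _ in range(max_steps):
        r2 = r + direction
        if r2 < 0 or r2 >= n_rows or (direction < 0 and r2 < row_limit) or (
            direction > 0 and r2 > row_limit
        ):
            break
        # candidate columns in preference order for HU ties: centre, left, right
        cand = [(r2, c), (r2, c - 1), (r2, c + 1)]
        cand = [(rr, cc) for rr, cc in cand if 0 <= cc < n_cols]
        best = max(cand, key=lambda p: (hu_slice[p], -cand.index(p)))
        r, c = best
        if lung_slice[r, c]:
            lung_slice[r, c] = False
            removed += 1
        else:
            break
    return removed


def separate_lungs(
    ct: CTVolume,
    lungs: np.ndarray,
    body: BodyMask,
) -> LungMask:
    """Separate fused lungs and label them left/right.

    On every slice whose widest lung component exceeds half the body width,
    anterior and posterior junction lines are walked from the largest
    non-lung component inside the junction ROI, relabelling traversed lung
    pixels as non-lung.  After all slices, 3D components (face
    connectivity, so the one-pixel junction cuts sever) are assigned to the
    patient's left or right by their column centroid relative to the body
    centroid.
    """
    lungs = np.asarray(lungs, dtype=bool).copy()
    check_congruent(lungs, body.mask)

    for k in range(lungs.shape[0]):
        body_bb = _bbox2d(body.mask[k])
        if body_bb is None or not lungs[k].any():
            continue
        body_width = body_bb[3] - body_bb[2] + 1
        labels, n = label_2d(lungs[k], connectivity=8)
        objects = ndi.find_objects(labels)
        for i, slc in enumerate(objects, start=1):
            comp_width = slc[1].stop - slc[1].start
            if comp_width <= body_width / 2:
                continue
            comp = labels == i
            bbox = (slc[0].start, slc[0].stop - 1, slc[1].start, slc[1].stop - 1)
            roi = junction_roi(bbox)
            _separate_component(ct.data[k], lungs[k], comp, roi)

    # per-slice assignment with in-plane 4-connectivity: the one-pixel
    # junction cut severs the slice, and its column may drift from slice
    # to slice, so 3D connectivity across the cut must not be trusted
    left = np.zeros_like(lungs)
    right = np.zeros_like(lungs)
    for k in range(lungs.shape[0]):
        if not lungs[k].any():
            continue
        centroid = body.centroid_2d(k)
        body_col = centroid[1] if centroid else lungs.shape[2] / 2
        labels, n = label_2d(lungs[k], connectivity=4)
        for i in range(1, n + 1):
            comp = labels == i
            # image left (smaller column) is the patient's right
            if np.nonzero(comp)[1].mean() < body_col:
                right[k] |= comp
            else:
                left[k] |= comp
    return LungMask(left=left, right=right)


def _bbox2d(mask: np.ndarray):
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        return None
    return int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1])


def _separate_component(hu_slice, lung_slice, comp, roi: JunctionROI) -> None:
    """Run the anterior and posterior junction walks for one fused component.

    The non-lung component search is restricted to the ROI and, to single
    out the mediastinal wedge under the anterior junction (rather than the
    anterior chest wall, which may be 8-connected to it around a narrow
    fusion), to non-lung pixels that have lung above them in their column.
    """
    window = lung_slice[roi.top : roi.bottom + 1, roi.left : roi.right + 1]
    covered_from_above = np.zeros_like(window)
    covered_from_above[1:] = np.logical_or.accumulate(window, axis=0)[:-1]
    sub = ~window & covered_from_above
    labels, n = label_2d(sub, connectivity=8)
    if n == 0:
        log.warning("no non-lung component in junction ROI; slice left unseparated")
        return
    counts = np.bincount(labels.ravel())[1:]
    nl = labels == (int(np.argmax(counts)) + 1)
    rows, cols = np.nonzero(nl)
    rows = rows + roi.top
    cols = cols + roi.left
    centre_col = (roi.left + roi.right) / 2
    max_steps = lung_slice.shape[0]

    # anterior: start at the minimum-row pixel nearest the ROI centre column
    top_rows = rows == rows.min()
    cand_cols = cols[top_rows]
    c0 = int(cand_cols[np.argmin(np.abs(cand_cols - centre_col))])
    _walk_junction(hu_slice, lung_slice, (int(rows.min()), c0), -1, 0, max_steps)

    # posterior: start at the maximum-row pixel nearest the ROI centre column
    bot_rows = rows == rows.max()
    cand_cols = cols[bot_rows]
    c1 = int(cand_cols[np.argmin(np.abs(cand_cols - centre_col))])
    _walk_junction(
        hu_slice, lung_slice, (int(rows.max()), c1), +1, lung_slice.shape[0] - 1, max_steps
    )


def interpolate_lungs(lungs: np.ndarray) -> np.ndarray:
    """Slice interpolation of a lung mask.

    Every pixel position (row, col) that is lung on any slice is labelled
    lung on all slices between the first and last slice (inclusive) where
    it is lung.  Idempotent.
    """
    lungs = np.asarray(lungs, dtype=bool)
    n = lungs.shape[0]
    any_col = lungs.any(axis=0)
    first = np.argmax(lungs, axis=0)
    last = n - 1 - np.argmax(lungs[::-1], axis=0)
    k = np.arange(n)[:, None, None]
    return any_col & (k >= first) & (k <= last)


def propagate_lung(
    lung: np.ndarray,
    neighborhood: int = 7,
    max_iter: int = 1000,
) -> np.ndarray:
    """Iterative neighbourhood propagation of one lung.

    In each iteration the candidates are the non-lung pixels within the
    in-slice ``neighborhood x neighborhood`` window of a lung border pixel;
    a candidate is admitted iff strictly more than half of the voxels in
    its 3D ``neighborhood^3`` window are lung.  All admitted candidates are
    added simultaneously; iteration stops at the fixed point.  The rule
    creeps over excluded pathology attached to the lung border (tumour
    notches, juxtapleural nodules) while flat or convex lung surfaces do
    not move.
    """
    lung = np.asarray(lung, dtype=bool).copy()
    m = int(neighborhood)
    half_count = (m ** 3) // 2  # admission requires count > half_count
    footprint2d = np.ones((1, m, m), dtype=bool)
    size3d = (m, m, m)
    for _ in range(max_iter):
        # non-lung pixels within the in-slice window of some border pixel
        near = ndi.binary_dilation(lung, structure=footprint2d)
        candidates = near & ~lung
        if not candidates.any():
            break
        counts = ndi.uniform_filter(
            lung.astype(np.float64), size=size3d, mode="constant", cval=0.0
        ) * (m ** 3)
        admitted = candidates & (np.rint(counts).astype(np.int64) > half_count)
        if not admitted.any():
            break
        lung |= admitted
    else:
        log.warning("lung propagation did not converge in %d iterations", max_iter)
    return lung


def include_pathology(lungs: LungMask, neighborhood: int = 7) -> LungMask:
    """Include excluded pathological areas into the lungs.

    Per lung: output = input ∪ (interpolated ∩ propagated), so the
    operator only ever adds voxels.  A voxel claimed by both lungs (never
    the case anatomically) is assigned to neither so the lungs stay
    disjoint.
    """
    add_left = (interpolate_lungs(lungs.left) & propagate_lung(lungs.left, neighborhood)) & ~lungs.left
    add_right = (interpolate_lungs(lungs.right) & propagate_lung(lungs.right, neighborhood)) & ~lungs.right
    conflict = add_left & add_right
    if conflict.any():
        log.warning("%d voxels claimed by both lungs; left unassigned", int(conflict.sum()))
    add_left &= ~conflict
    add_right &= ~conflict
    add_left &= ~lungs.right
    add_right &= ~lungs.left
    return LungMask(left=lungs.left | add_left, right=lungs.right | add_right)
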