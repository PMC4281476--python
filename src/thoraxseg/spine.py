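"""Vertebra and spinal-canal segmentation.

Bone is thresholded at 145 HU inside the body; components larger than
25 mm^2 lying at least 10 px from the body border are accepted.  The
vertebra is the bone overlapping an anatomical ROI around the posterior
body midline.  The spinal canal is then taken directly as the non-bone
region enclosed by the vertebral ring on slices where the ring is closed;
on the remaining slices it is recovered by fuzzy segmentation with
grayscale morphological reconstruction, seeded from the canal centre of
the nearest processed slice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import sobel
from skimage.morphology import reconstruction

from ._util import DISK3, STRUCT_2D_4, STRUCT_2D_8, label_2d, largest_component
from .body import BodyMask
from .volume import CTVolume

log = logging.getLogger(__name__)

__all__ = [
    "FuzzyParams",
    "VertebraMask",
    "SpinalCanalResult",
    "CanalLostError",
    "segment_bone",
    "segment_vertebra",
    "check_enclosed",
    "fuzzy_canal_slice",
    "segment_spinal_canal",
]


class CanalLostError(RuntimeError):
    """Fuzzy propagation found no candidate canal pixel in the window."""


@dataclass(frozen=True)
class FuzzyParams:
    """Parameters of the fuzzy spinal-canal segmentation.

    ``mu_prior``/``sigma_prior`` describe the expected canal density
    (cerebrospinal fluid / cord, ~23 +/- 15 HU); candidate seed pixels must
    fall within ``mu_prior +/- k * sigma_prior``.  The slice-specific
    statistics (mu_SP, sigma_SP) are re-estimated from the seed pixels in
    an in-slice square window.
    """

    mu_prior: float = 23.0
    sigma_prior: float = 15.0
    k: float = 2.5
    window: int = 11
    binarize_threshold: float = 0.5

    @property
    def prior_range(self) -> tuple[float, float]:
        half = self.k * self.sigma_prior
        return self.mu_prior - half, self.mu_prior + half


@dataclass
class VertebraMask:
    """Per-slice vertebra mask with bounding boxes."""

    mask: np.ndarray
    bboxes: dict[int, tuple[int, int, int, int]] = field(default_factory=dict)


def segment_bone(
    ct: CTVolume,
    body: BodyMask,
    threshold_hu: float = 145.0,
    min_area_mm2: float = 25.0,
    min_border_distance_px: float = 10.0,
) -> np.ndarray:
    """Per-slice bone segments inside the body.

    Components of {HU > threshold} are accepted when their area exceeds
    ``min_area_mm2`` and every pixel lies at least
    ``min_border_distance_px`` pixels from the body border (which rejects
    skin-adjacent artefacts and peripheral ribs).
    """
    pixel_area = ct.pixel_area_mm2
    fg = (ct.data > threshold_hu) & body.mask
    out = np.zeros(ct.shape, dtype=bool)
    for k in range(ct.n_slices):
        if not fg[k].any():
            continue
        # pad so the image edge counts as body border
        padded = np.pad(body.mask[k], 1)
        dist = ndi.distance_transform_edt(padded)[1:-1, 1:-1]
        labels, n = label_2d(fg[k], connectivity=8)
        for i in range(1, n + 1):
            comp = labels == i
            if comp.sum() * pixel_area <= min_area_mm2:
                continue
            if dist[comp].min() < min_border_distance_px:
                continue
            out[k] |= comp
    return out


def _vertebra_roi(body_slice: np.ndarray) -> tuple[int, int, int, int] | None:
    """(top, bottom, left, right) vertebra-search ROI from the body bbox."""
    rows = np.flatnonzero(body_slice.any(axis=1))
    cols = np.flatnonzero(body_slice.any(axis=0))
    if rows.size == 0:
        return None
    top, bottom = int(rows[0]), int(rows[-1])
    left, right = int(cols[0]), int(cols[-1])
    cp_row = (top + bottom) // 2
    cp_col = (left + right) // 2
    return cp_row - 50, bottom - 10, cp_col - 10, cp_col + 10


def segment_vertebra(
    bone: np.ndarray,
    body: BodyMask,
    ct: CTVolume,
    recovery_min_hu: float = 100.0,
) -> VertebraMask:
    """Label the vertebra among the bone segments of each slice.

    Bone components overlapping the anatomical ROI (a narrow band around
    the posterior body midline) become vertebra; the sternum and ribs fall
    outside it.  Missing parts (edge pixels whose HU dropped below the
    bone threshold through partial-volume averaging) are recovered by
    adding pixels that are 8-adjacent to the vertebra, carry a non-zero CT
    gradient magnitude and are at least ``recovery_min_hu`` dense — the HU
    floor keeps the recovery from absorbing canal or soft-tissue pixels.
    """
    n_slices = ct.n_slices
    out = np.zeros(ct.shape, dtype=bool)
    bboxes: dict[int, tuple[int, int, int, int]] = {}
    for k in range(n_slices):
        roi = _vertebra_roi(body.mask[k])
        if roi is None or not bone[k].any():
            continue
        top, bottom, left, right = roi
        top = max(top, 0)
        left = max(left, 0)
        bottom = min(bottom, ct.n_rows - 1)
        right = min(right, ct.n_cols - 1)
        roi_mask = np.zeros(bone[k].shape, dtype=bool)
        roi_mask[top : bottom + 1, left : right + 1] = True
        labels, n = label_2d(bone[k], connectivity=8)
        vert = np.zeros_like(roi_mask)
        for i in range(1, n + 1):
            comp = labels == i
            if (comp & roi_mask).any():
                vert |= comp
        if not vert.any():
            log.warning("slice %d: no bone segment overlaps the vertebra ROI", k)
            continue
        # recover missing (partial-volume) parts adjacent to the vertebra
        grad = sobel(ct.data[k].astype(np.float64))
        adjacent = ndi.binary_dilation(vert, structure=STRUCT_2D_8) & ~vert
        vert |= adjacent & (grad > 0) & (ct.data[k] >= recovery_min_hu)
        out[k] = vert
        rows = np.flatnonzero(vert.any(axis=1))
        cols = np.flatnonzero(vert.any(axis=0))
        bboxes[k] = (int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1]))
    return VertebraMask(mask=out, bboxes=bboxes)


def check_enclosed(vertebra_slice: np.ndarray) -> tuple[bool, np.ndarray | None]:
    """Test whether the vertebral ring of one slice encloses the canal.

    Within the vertebra bounding box, non-bone components are labelled
    with 4-connectivity (so a diagonal gap in the ring counts as open);
    if some component touches no bounding-box border the slice is
    enclosed and the largest such component is the canal region.
    """
    vertebra_slice = np.asarray(vertebra_slice, dtype=bool)
    rows = np.flatnonzero(vertebra_slice.any(axis=1))
    cols = np.flatnonzero(vertebra_slice.any(axis=0))
    if rows.size == 0:
        return False, None
    top, bottom, left, right = int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1])
    window = vertebra_slice[top : bottom + 1, left : right + 1]
    labels, n = ndi.label(~window, structure=STRUCT_2D_4)
    if n == 0:
        return False, None
    border_labels = set(labels[0]) | set(labels[-1]) | set(labels[:, 0]) | set(labels[:, -1])
    best = None
    for i in range(1, n + 1):
        if i in border_labels:
            continue
        size = int((labels == i).sum())
        if best is None or size > best[0]:
            best = (size, i)
    if best is None:
        return False, None
    out = np.zeros_like(vertebra_slice)
    out[top : bottom + 1, left : right + 1] = labels == best[1]
    return True, out


def fuzzy_canal_slice(
    ct_slice: np.ndarray,
    seed_cp: tuple[int, int],
    params: FuzzyParams = FuzzyParams(),
) -> np.ndarray:
    """Fuzzy segmentation of the spinal canal on one slice.

    Pixels of an in-slice window centred at ``seed_cp`` falling within the
    prior density range become the seeds; their mean/SD parameterize an
    unnormalized Gaussian membership image which is reconstructed from the
    seeds by grayscale morphological reconstruction, binarized at
    ``binarize_threshold``, reduced to its largest component and opened
    with a 3x3 disk.
    """
    ct_slice = np.asarray(ct_slice, dtype=np.float64)
    n_rows, n_cols = ct_slice.shape
    r, c = int(seed_cp[0]), int(seed_cp[1])
    if not (0 <= r < n_rows and 0 <= c < n_cols):
        raise IndexError(f"seed {seed_cp} outside slice of shape {ct_slice.shape}")
    half = params.window // 2
    r0, r1 = max(r - half, 0), min(r + half + 1, n_rows)
    c0, c1 = max(c - half, 0), min(c + half + 1, n_cols)
    lo, hi = params.prior_range
    window = ct_slice[r0:r1, c0:c1]
    selected = (window >= lo) & (window <= hi)
    if not selected.any():
        raise CanalLostError("no pixel in the prior HU range within the seed window")
    values = window[selected]
    mu_sp = float(values.mean())
    sigma_sp = float(values.std())
    if sigma_sp <= 0 or values.size < 2:
        sigma_sp = params.sigma_prior  # degenerate estimate: fall back to the prior

    membership = np.exp(-((ct_slice - mu_sp) ** 2) / (2.0 * sigma_sp ** 2))
    marker = np.zeros_like(membership)
    seeds = np.zeros_like(membership, dtype=bool)
    seeds[r0:r1, c0:c1] = selected
    marker[seeds] = membership[seeds]
    recon = reconstruction(marker, membership, method="dilation")  # 8-connected

    binarized = recon >= params.binarize_threshold
    labels, n = label_2d(binarized, connectivity=8)
    canal = largest_component(labels, n)
    return ndi.binary_opening(canal, structure=DISK3)


def _centroid_px(mask: np.ndarray) -> tuple[int, int]:
    rr, cc = np.nonzero(mask)
    return int(round(rr.mean())), int(round(cc.mean()))


@dataclass
class SpinalCanalResult:
    """Canal mask plus per-slice provenance diagnostics."""

    mask: np.ndarray
    #: per slice: "enclosed", "fuzzy", or "empty"
    slice_source: list[str] = field(default_factory=list)
    fuzzy_calls: int = 0


def segment_spinal_canal(
    ct: CTVolume,
    vertebra: VertebraMask,
    params: FuzzyParams = FuzzyParams(),
) -> SpinalCanalResult:
    """Segment the spinal canal across the whole scan.

    Slices whose vertebral ring encloses the canal take the enclosed
    non-bone region directly.  The remaining slices are processed outward
    from the enclosed ones, each seeded with the canal centre point of the
    adjacent already-processed slice and segmented by
    :func:`fuzzy_canal_slice`.  Bone pixels are never part of the canal.
    """
    n = ct.n_slices
    out = np.zeros(ct.shape, dtype=bool)
    source = ["empty"] * n
    fuzzy_calls = 0

    for k in range(n):
        enclosed, region = check_enclosed(vertebra.mask[k])
        if enclosed:
            out[k] = region
            source[k] = "enclosed"
    if not any(s == "enclosed" for s in source):
        raise RuntimeError("cannot initialize: no slice has a fully enclosed spinal canal")

    def _try_fuzzy(k: int, neighbor: int) -> None:
        nonlocal fuzzy_calls
        seed = _centroid_px(out[neighbor])
        try:
            fuzzy_calls += 1
            canal = fuzzy_canal_slice(ct.data[k], seed, params)
        except CanalLostError:
            log.warning("slice %d: spinal canal lost during fuzzy propagation", k)
            return
        canal &= ~vertebra.mask[k]
        if canal.any():
            out[k] = canal
            source[k] = "fuzzy"

    # propagate inferiorly then superiorly from every processed slice
    for k in range(1, n):
        if source[k] == "empty" and source[k - 1] != "empty":
            _try_fuzzy(k, k - 1)
    for k in range(n - 2, -1, -1):
        if source[k] == "empty" and source[k + 1] != "empty":
            _try_fuzzy(k, k + 1)

    return SpinalCanalResult(mask=out, slice_source=source, fuzzy_calls=fuzzy_calls)
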