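"""Small shared morphology helpers."""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

# The 3x3 "disk" structuring element used by every per-slice morphological
# step (dilation, closing, opening).  A disk of diameter 3 (radius 1.5)
# rasterizes to the full 3x3 square: the corner pixels lie at distance
# sqrt(2) ~ 1.41 < 1.5 from the centre.
DISK3 = np.ones((3, 3), dtype=bool)

# 2D connectivity structures.
STRUCT_2D_8 = np.ones((3, 3), dtype=bool)
STRUCT_2D_4 = np.array(
    [[0, 1, 0],
     [1, 1, 1],
     [0, 1, 0]],
    dtype=bool,
)

# 3D connectivity structures.
STRUCT_3D_26 = np.ones((3, 3, 3), dtype=bool)
STRUCT_3D_6 = ndi.generate_binary_structure(3, 1)
STRUCT_3D_18 = ndi.generate_binary_structure(3, 2)


def label_2d(mask: np.ndarray, connectivity: int = 8):
    """Label a 2D boolean mask; returns (labels, n)."""
    struct = STRUCT_2D_8 if connectivity == 8 else STRUCT_2D_4
    return ndi.label(mask, structure=struct)


def fill_holes_2d(mask: np.ndarray) -> np.ndarray:
    """Fill interior holes of a 2D mask.

    The background flood uses 4-connectivity (scipy default), so diagonal
    gaps in the foreground do not leak filling.
    """
    return ndi.binary_fill_holes(mask)


def largest_component(labels: np.ndarray, n: int) -> np.ndarray:
    """Boolean mask of the largest labelled component (empty if n == 0)."""
    if n == 0:
        return np.zeros_like(labels, dtype=bool)
    counts = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(counts)) + 1)


def bounding_box_2d(mask: np.ndarray) -> tuple[int, int, int, int] | None:
    """(top, bottom, left, right) inclusive bounds of a 2D mask, or None."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        return None
    return int(rows[0]), int(rows[-1]), int(cols[0]), int(cols[-1])
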