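"""Canonical in-memory containers for CT volumes and label maps.

Axis convention used throughout the package:

* arrays are indexed ``(slice, row, col)``;
* slice index 0 is the most **superior** (cranial) slice;
* row index 0 is the **anterior** image border;
* column index 0 is the image left, i.e. the **patient's right** side
  (radiological display convention);
* ``spacing`` is the physical step per axis in the same order,
  ``(slice_thickness_mm, pixel_height_mm, pixel_width_mm)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Integer labels written by the full pipeline.
LABELS = {
    0: "background",
    1: "body",
    2: "right_lung",
    3: "left_lung",
    4: "trachea_bronchi",
    5: "bone",
    6: "spinal_canal",
}
LABEL_IDS = {name: i for i, name in LABELS.items()}


class GeometryError(ValueError):
    """Raised when image geometry (spacing, shape, orientation) is invalid."""


class FormatError(ValueError):
    """Raised when an input file/series cannot be interpreted as a CT volume."""


@dataclass
class CTVolume:
    """A 3D CT volume in Hounsfield units.

    Parameters
    ----------
    data
        3D array of HU values, indexed ``(slice, row, col)`` with the most
        superior slice first.
    spacing
        Physical voxel spacing in mm per axis,
        ``(slice_thickness, pixel_height, pixel_width)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be 3 positive floats, got {self.spacing!r}")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def n_rows(self) -> int:
        return self.data.shape[1]

    @property
    def n_cols(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def pixel_area_mm2(self) -> float:
        """In-plane area of one pixel (mm^2)."""
        return self.spacing[1] * self.spacing[2]

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]


@dataclass
class LabelVolume:
    """Integer label map sharing the geometry of a :class:`CTVolume`.

    Label 0 is reserved for background.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    label_names: dict[int, str] = field(default_factory=lambda: dict(LABELS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise GeometryError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise GeometryError("labels must have an integer dtype")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError("spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, label: int | str) -> np.ndarray:
        """Boolean mask of one structure, by integer label or name."""
        if isinstance(label, str):
            matches = [i for i, n in self.label_names.items() if n == label]
            if not matches:
                raise KeyError(f"unknown structure name {label!r}")
            label = matches[0]
        return self.labels == label


def check_congruent(a: np.ndarray, b: np.ndarray) -> None:
    """Validate that two masks/volumes share a shape."""
    if a.shape != b.shape:
        raise GeometryError(f"incongruent shapes: {a.shape} vs {b.shape}")
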