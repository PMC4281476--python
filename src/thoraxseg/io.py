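"""Reading and writing CT volumes, label maps and metric reports.

Supported inputs are a DICOM series directory or a NIfTI file; outputs are
integer NIfTI label maps and CSV/JSON metric tables.  Loaded volumes are
reordered into the package's canonical orientation (superior slice first;
see :mod:`thoraxseg.volume`).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .metrics import MetricReport
from .volume import CTVolume, FormatError, GeometryError, LabelVolume, LABELS

__all__ = [
    "load_ct",
    "load_nifti",
    "load_dicom_dir",
    "save_labels",
    "load_labels",
    "save_metrics",
]


def _nifti_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    # RAS+ affine for data stored as (x, y, z) after the canonical transpose
    sz, sy, sx = spacing
    return np.diag([sx, sy, sz, 1.0])


def _to_canonical(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Reorient a NIfTI image into (slice, row, col), superior first."""
    img = nib.as_closest_canonical(img)  # RAS+: +x right, +y anterior, +z superior
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise GeometryError(f"non-positive voxel size {zooms}")
    # RAS (x, y, z) -> (slice = -z, row = -y, col = -x)
    vol = data.transpose(2, 1, 0)[::-1, ::-1, ::-1]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return np.ascontiguousarray(vol), spacing


def load_nifti(path: str | Path) -> CTVolume:
    """Load a NIfTI volume (HU values) into the canonical orientation."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    data, spacing = _to_canonical(img)
    return CTVolume(data=data.astype(np.float64), spacing=spacing)


def load_dicom_dir(path: str | Path) -> CTVolume:
    """Load a DICOM series directory into the canonical orientation.

    Slices are sorted superior-first by ImagePositionPatient; the rescale
    slope/intercept converts stored values to HU.
    """
    import pydicom

    path = Path(path)
    datasets = []
    for f in sorted(path.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if not hasattr(ds, "PixelData"):
            continue
        datasets.append(ds)
    if not datasets:
        raise FormatError(f"no readable DICOM slices in {path}")
    modality = getattr(datasets[0], "Modality", "CT")
    if modality not in ("CT", ""):
        raise FormatError(f"modality {modality!r} is not CT")

    def z_position(ds):
        try:
            return float(ds.ImagePositionPatient[2])
        except Exception:
            return float(getattr(ds, "InstanceNumber", 0))

    # DICOM +z points toward the head: superior-first means descending z
    datasets.sort(key=z_position, reverse=True)

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    data = np.stack(slices, axis=0)

    ps = getattr(datasets[0], "PixelSpacing", None)
    if ps is None:
        raise GeometryError("DICOM series lacks PixelSpacing")
    if len(datasets) > 1:
        zs = [z_position(ds) for ds in datasets]
        dz = np.abs(np.diff(zs))
        if dz.max() - dz.min() > 0.01:
            raise GeometryError("inconsistent DICOM slice spacing")
        thickness = float(dz.mean())
    else:
        thickness = float(getattr(datasets[0], "SliceThickness", 1.0))
    if thickness <= 0:
        raise GeometryError("non-positive slice spacing")
    return CTVolume(data=data, spacing=(thickness, float(ps[0]), float(ps[1])))


def load_ct(path: str | Path, format: str | None = None) -> CTVolume:
    """Load a CT volume from a NIfTI file or DICOM series directory.

    ``format`` may be ``"nifti"`` or ``"dicom_dir"``; by default it is
    inferred from the path (directory → DICOM).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "dicom_dir" if path.is_dir() else "nifti"
    if format == "nifti":
        return load_nifti(path)
    if format == "dicom_dir":
        return load_dicom_dir(path)
    raise ValueError(f"unknown format {format!r}")


def save_labels(vol: LabelVolume, path: str | Path) -> None:
    """Write a label volume as integer NIfTI; reload is bit-identical."""
    path = Path(path)
    labels = vol.labels
    if labels.shape != tuple(vol.shape):
        raise GeometryError("label array inconsistent with declared geometry")
    # canonical (slice,row,col) -> RAS (x,y,z)
    data = labels[::-1, ::-1, ::-1].transpose(2, 1, 0)
    img = nib.Nifti1Image(np.ascontiguousarray(data.astype(np.int16)), _nifti_affine(vol.spacing))
    nib.save(img, str(path))


def load_labels(path: str | Path) -> LabelVolume:
    """Load an integer NIfTI label map."""
    img = nib.load(str(Path(path)))
    data, spacing = _to_canonical(img)
    return LabelVolume(
        labels=np.rint(data).astype(np.int16), spacing=spacing, label_names=dict(LABELS)
    )


def save_metrics(reports: list[MetricReport], path: str | Path) -> None:
    """Write metric reports as CSV or JSON (chosen by file extension)."""
    path = Path(path)
    rows = [r.as_dict() for r in reports]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=2))
    else:
        pd.DataFrame(rows, columns=["structure", "vor_pct", "asd_mm", "rmsd_mm", "msd_mm"]).to_csv(
            path, index=False
        )
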