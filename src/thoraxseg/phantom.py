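"""Digital thorax phantom generation.

The phantom rasterizes analytic solids on a voxel grid: an elliptical
soft-tissue body on an air background, two ellipsoidal lung fields, a
branching air tube (trachea + main bronchi) with a denser wall, a vertebral
bone ring enclosing a soft-tissue spinal canal, and optionally pleural /
juxtapleural / interior tumours, an anterior lung fusion, an opened ring on
selected slices, and a disconnected caudal bowel-gas pocket.  Tissue HU
means are chosen so every structure triggers the segmentation threshold it
must trigger (lung below -300 HU, bone above 145 HU, airway lumen below
-900 HU, body inside [-175, 750] HU).

Noise is seeded, Gaussian per tissue and mildly spatially correlated
(CT noise is not white); geometry is deterministic given the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi

from .volume import CTVolume, LabelVolume, LABELS
from ._util import STRUCT_3D_26

__all__ = ["TumorSpec", "PhantomSpec", "PhantomTruth", "generate_phantom", "preset"]


@dataclass(frozen=True)
class TumorSpec:
    """One tumour: sphere of ``radius_mm`` centred at voxel ``center``
    (slice, row, col), clipped to the lung envelope for pleural/juxtapleural
    attachment."""

    center: tuple[int, int, int]
    radius_mm: float
    hu: float = 30.0
    attachment: str = "pleural"  # pleural | juxtapleural | interior


@dataclass
class PhantomSpec:
    """Geometry, tissue densities and noise of a synthetic thorax."""

    # 128x128 in-plane at 2 mm pixels: a full-size ~230 mm-wide thorax on a
    # grid coarse enough for fast tests (a 512x512 scan downsampled 4x)
    shape: tuple[int, int, int] = (60, 128, 128)  # (slices, rows, cols)
    spacing: tuple[float, float, float] = (2.5, 2.0, 2.0)  # mm, (slice, row, col)
    seed: int = 0

    # tissue mean HU
    air_hu: float = -1000.0
    body_hu: float = 30.0
    lung_hu: float = -850.0
    lumen_hu: float = -1000.0
    # airway wall: soft-tissue-like, denser than lumen and parenchyma and
    # above the -300 HU lung threshold (as in real scans)
    wall_hu: float = -100.0
    bone_hu: float = 300.0
    canal_mu_hu: float = 23.0
    bowel_gas_hu: float = -950.0

    # noise standard deviations (HU)
    body_noise_sd: float = 20.0
    lung_noise_sd: float = 30.0
    lumen_noise_sd: float = 20.0
    wall_noise_sd: float = 10.0
    bone_noise_sd: float = 30.0
    canal_sigma_hu: float = 5.0
    noise_correlation_px: float = 0.8

    # geometry (voxel units unless noted)
    body_center: tuple[int, int] = (64, 64)  # (row, col)
    body_semi_axes: tuple[int, int] = (48, 58)  # (row, col)
    lung_center_row: int = 60
    lung_center_cols: tuple[int, int] = (38, 90)  # (patient-right, patient-left)
    lung_semi_axes: tuple[float, float, float] = (24.0, 34.0, 20.0)  # (slice, row, col)
    lung_center_slice: int = 32
    trachea_center: tuple[int, int] = (56, 64)  # (row, col)
    trachea_radius_px: float = 4.5  # ~18 mm lumen diameter at 2 mm pixels
    bronchus_radius_px: float = 3.5
    bronchus_end_radius_px: float = 2.2  # bronchi taper toward the periphery
    carina_slice: int = 16
    bronchi_end_slice: int = 30
    # bronchi run along the medial lung borders (hilum): partly embedded,
    # open to the mediastinum, as in real anatomy
    bronchi_end_cols: tuple[int, int] = (57, 71)
    wall_thickness_px: int = 1
    ring_center: tuple[int, int] = (89, 64)  # (row, col)
    ring_outer_px: float = 12.0  # vertebra ~48 mm wide
    ring_inner_px: float = 5.0  # spinal canal ~20 mm wide

    # variants
    tumors: list[TumorSpec] = field(default_factory=list)
    #: relative radial surface roughness of tumours (real GTVs are lumpy,
    #: not perfect spheres); 0 gives exact spheres
    tumor_roughness: float = 0.1
    fuse_lungs_anteriorly: bool = False
    open_ring_slices: tuple[int, ...] = ()
    include_bowel_gas: bool = True
    bowel_center: tuple[int, int, int] = (55, 70, 60)
    bowel_radius_px: float = 8.0

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValueError("phantom shape too small")
        for t in self.tumors:
            if t.attachment not in ("pleural", "juxtapleural", "interior"):
                raise ValueError(f"unknown tumor attachment {t.attachment!r}")
            if not all(0 <= t.center[i] < self.shape[i] for i in range(3)):
                raise ValueError(f"tumor center {t.center} outside the volume")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhantomTruth:
    """Ground-truth masks of one phantom.

    ``labels`` holds the expected *final* segmentation: tumours are part of
    the lungs there (pathology must be included).  The individual masks
    separate lumen/wall and pathology-free lungs for stage-level tests.
    """

    labels: LabelVolume
    body: np.ndarray
    left_lung: np.ndarray  # includes attached tumours (expected final)
    right_lung: np.ndarray
    left_lung_parenchyma: np.ndarray  # without tumours
    right_lung_parenchyma: np.ndarray
    lumen: np.ndarray
    wall: np.ndarray
    bone: np.ndarray
    canal: np.ndarray
    tumor: np.ndarray

    @property
    def lungs(self) -> np.ndarray:
        return self.left_lung | self.right_lung

    @property
    def airway(self) -> np.ndarray:
        return self.lumen | self.wall


def _disk2d(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _tube(shape, centers_rc, radius, z0, z1):
    """Rasterize a tube from slice z0..z1 (inclusive) with per-slice centres."""
    out = np.zeros(shape, dtype=bool)
    for z in range(z0, z1 + 1):
        out[z] = _disk2d(shape[1:], centers_rc(z), radius)
    return out


def generate_phantom(spec: PhantomSpec | None = None) -> tuple[CTVolume, PhantomTruth]:
    """Rasterize a phantom and its ground truth.  Deterministic given
    ``spec`` (including its seed)."""
    spec = spec or PhantomSpec()
    spec.validate()
    nz, ny, nx = spec.shape
    shape = spec.shape

    rr, cc = np.ogrid[:ny, :nx]
    body2d = (
        ((rr - spec.body_center[0]) / spec.body_semi_axes[0]) ** 2
        + ((cc - spec.body_center[1]) / spec.body_semi_axes[1]) ** 2
    ) <= 1.0
    body = np.broadcast_to(body2d, shape).copy()

    zz = np.arange(nz)[:, None, None]
    ry, rx = rr[None, :, :], cc[None, :, :]
    az, ay, ax = spec.lung_semi_axes
    lungs_env = []
    for col in spec.lung_center_cols:
        # blunt-ended superellipsoid: lungs are not pointed at apex/base,
        # and the most cranial/caudal cross sections stay anatomically large
        env = (
            ((zz - spec.lung_center_slice) / az) ** 4
            + ((ry - spec.lung_center_row) / ay) ** 2
            + ((rx - col) / ax) ** 2
        ) <= 1.0
        lungs_env.append(env)
    right_env, left_env = lungs_env  # patient right = smaller column

    # airway tree: trachea + two bronchi, each a tube of air
    tr, tc = spec.trachea_center
    lumen = _tube(shape, lambda z: (tr, tc), spec.trachea_radius_px, 0, spec.carina_slice)
    span = max(spec.bronchi_end_slice - spec.carina_slice, 1)
    for col in spec.bronchi_end_cols:
        for z in range(spec.carina_slice, spec.bronchi_end_slice + 1):
            f = (z - spec.carina_slice) / span
            center = (tr + (spec.lung_center_row - tr) * f * 0.5, tc + (col - tc) * f)
            radius = spec.bronchus_radius_px + f * (
                spec.bronchus_end_radius_px - spec.bronchus_radius_px
            )
            lumen[z] |= _disk2d((ny, nx), center, radius)
    wall = (
        ndi.binary_dilation(lumen, structure=STRUCT_3D_26, iterations=spec.wall_thickness_px)
        & ~lumen
    )

    # anterior fusion: on each slice of the fusion range, a lung-density
    # bridge spanning the gap between the two lung edges in an anterior
    # row band, so the lungs form one in-plane connected component there
    fusion = np.zeros(shape, dtype=bool)
    if spec.fuse_lungs_anteriorly:
        z0 = max(0, spec.lung_center_slice - 10)
        z1 = min(nz - 1, spec.lung_center_slice + 6)
        band = slice(48, 55)
        for z in range(z0, z1 + 1):
            rband = right_env[z, band, :]
            lband = left_env[z, band, :]
            if not rband.any() or not lband.any():
                continue
            c_right = int(np.nonzero(rband.any(axis=0))[0].max())
            c_left = int(np.nonzero(lband.any(axis=0))[0].min())
            if c_left - c_right >= 2:
                fusion[z, band, c_right : c_left + 1] = True
        fusion &= body & ~lumen & ~wall

    right_par = (right_env | (fusion & (rx < spec.body_center[1]))) & ~lumen & ~wall
    left_par = (left_env | (fusion & (rx >= spec.body_center[1]))) & ~lumen & ~wall

    # vertebral ring and canal
    ring2d = _disk2d((ny, nx), spec.ring_center, spec.ring_outer_px) & ~_disk2d(
        (ny, nx), spec.ring_center, spec.ring_inner_px
    )
    canal2d = _disk2d((ny, nx), spec.ring_center, spec.ring_inner_px)
    bone = np.broadcast_to(ring2d, shape).copy()
    canal = np.broadcast_to(canal2d, shape).copy()
    for z in spec.open_ring_slices:
        gap = (rr > spec.ring_center[0]) & (np.abs(cc - spec.ring_center[1]) <= 3)
        bone[z] &= ~np.asarray(gap)

    # tumours: lumpy spheres (radius in mm on the anisotropic grid, with a
    # seeded smooth radial perturbation), clipped to the lung envelope —
    # they displace lung tissue
    tumor = np.zeros(shape, dtype=bool)
    lung_env_all = right_env | left_env
    sz, sy, sx = spec.spacing
    rough = None
    if spec.tumors and spec.tumor_roughness > 0:
        rough_rng = np.random.default_rng(spec.seed + 1)
        rough = ndi.gaussian_filter(rough_rng.standard_normal(shape), 3.0)
        rough /= rough.std() or 1.0
    for t in spec.tumors:
        d = np.sqrt(
            ((zz - t.center[0]) * sz) ** 2
            + ((ry - t.center[1]) * sy) ** 2
            + ((rx - t.center[2]) * sx) ** 2
        )
        radius = t.radius_mm
        if rough is not None:
            radius = t.radius_mm * (1.0 + spec.tumor_roughness * rough)
        sphere = (d <= radius) & lung_env_all
        if not sphere.any():
            raise ValueError(f"tumor at {t.center} does not intersect the lungs")
        tumor |= sphere
    tumor &= ~lumen & ~wall
    right_par &= ~tumor
    left_par &= ~tumor

    bowel = np.zeros(shape, dtype=bool)
    if spec.include_bowel_gas:
        bz, br, bc = spec.bowel_center
        bowel = (
            ((zz - bz)) ** 2 + ((ry - br)) ** 2 + ((rx - bc)) ** 2
        ) <= spec.bowel_radius_px ** 2
        # keep a 2-voxel clearance so bowel gas never touches the lungs
        clearance = ndi.binary_dilation(lung_env_all, structure=STRUCT_3D_26, iterations=2)
        bowel &= body & ~clearance & ~bone & ~canal & ~lumen & ~wall

    # ---- compose HU volume --------------------------------------------
    rng = np.random.default_rng(spec.seed)

    def noise(sd: float) -> np.ndarray:
        white = rng.standard_normal(shape)
        if spec.noise_correlation_px > 0:
            smooth = ndi.gaussian_filter(white, spec.noise_correlation_px)
            smooth /= smooth.std() or 1.0
            white = smooth
        return white * sd

    hu = np.full(shape, spec.air_hu, dtype=np.float64) + noise(spec.body_noise_sd)
    for mask, mean, sd in (
        (body, spec.body_hu, spec.body_noise_sd),
        (right_par | left_par, spec.lung_hu, spec.lung_noise_sd),
        (fusion, spec.lung_hu, spec.lung_noise_sd),
        (tumor, None, spec.body_noise_sd),
        (bowel, spec.bowel_gas_hu, spec.body_noise_sd),
        (wall, spec.wall_hu, spec.wall_noise_sd),
        (lumen, spec.lumen_hu, spec.lumen_noise_sd),
        (bone, spec.bone_hu, spec.bone_noise_sd),
        (canal, spec.canal_mu_hu, spec.canal_sigma_hu),
    ):
        if not mask.any():
            continue
        mean_val = mean
        if mean_val is None:  # tumours: per-tumour HU
            continue
        hu[mask] = mean_val + noise(sd)[mask]
    for t in spec.tumors:
        d2 = (
            ((zz - t.center[0]) * sz) ** 2
            + ((ry - t.center[1]) * sy) ** 2
            + ((rx - t.center[2]) * sx) ** 2
        )
        m = (d2 <= t.radius_mm ** 2) & tumor
        hu[m] = t.hu + noise(spec.body_noise_sd)[m]

    ct = CTVolume(data=hu, spacing=spec.spacing)

    # ---- truth labels (expected final segmentation) -------------------
    right_final = right_par | (tumor & (rx < spec.body_center[1]))
    left_final = left_par | (tumor & (rx >= spec.body_center[1]))
    labels = np.zeros(shape, dtype=np.int16)
    labels[body] = 1
    labels[right_final] = 2
    labels[left_final] = 3
    labels[lumen | wall] = 4
    labels[bone] = 5
    labels[canal & ~bone] = 6
    truth = PhantomTruth(
        labels=LabelVolume(labels=labels, spacing=spec.spacing, label_names=dict(LABELS)),
        body=body,
        left_lung=left_final,
        right_lung=right_final,
        left_lung_parenchyma=left_par,
        right_lung_parenchyma=right_par,
        lumen=lumen,
        wall=wall,
        bone=bone,
        canal=canal & ~bone,
        tumor=tumor,
    )
    return ct, truth


# ---------------------------------------------------------------------------

#: GTV range observed clinically (cc); used by the tumour presets.
GTV_RANGE_CC = (16.4, 93.2)


def _radius_mm_for_cc(volume_cc: float) -> float:
    return float((3.0 * volume_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def preset(name: str, seed: int = 0, **overrides) -> PhantomSpec:
    """Named phantom presets.

    ``clean``: pathology-free thorax; ``fused``: anterior lung fusion;
    ``tumor-small`` / ``tumor-large``: pleural tumours at the ends of the
    clinical GTV range (16.4 and 93.2 cc); ``nodule``: a juxtapleural
    nodule of 8 mm diameter; ``open-ring``: vertebral ring opened on the
    three most superior slices.
    """
    spec = PhantomSpec(seed=seed)
    if name == "clean":
        pass
    elif name == "fused":
        spec.fuse_lungs_anteriorly = True
    elif name == "tumor-small":
        r = _radius_mm_for_cc(GTV_RANGE_CC[0])
        spec.tumors = [TumorSpec(center=(32, 60, 52), radius_mm=r)]
    elif name == "tumor-large":
        r = _radius_mm_for_cc(GTV_RANGE_CC[1])
        spec.tumors = [TumorSpec(center=(32, 60, 46), radius_mm=r)]
    elif name == "nodule":
        spec.tumors = [
            TumorSpec(center=(32, 60, 55), radius_mm=4.0, attachment="juxtapleural")
        ]
    elif name == "open-ring":
        spec.open_ring_slices = (0, 1, 2)
    else:
        raise ValueError(f"unknown preset {name!r}")
    for k, v in overrides.items():
        setattr(spec, k, v)
    return spec
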