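"""End-to-end orchestration: body → lungs/airway → spine.

The three processes run in the order body segmentation; rough lung fields,
airway segmentation and removal, lung correction/separation/pathology
inclusion; bone, vertebra and spinal-canal segmentation.  A failing stage
is reported with its name while stages for unaffected structures continue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import airway as _airway
from . import body as _body
from . import lungs as _lungs
from . import spine as _spine
from .spine import FuzzyParams
from .volume import CTVolume, LabelVolume, LABELS, LABEL_IDS

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, at its default value."""

    # body
    body_hu_low: float = -175.0
    body_hu_high: float = 750.0
    body_min_area_mm2: float = 800.0
    # airway
    n_top_slices: int = 5
    seed_air_hu: float = -900.0
    seed_min_area_mm2: float = 20.0
    grow_initial_threshold: int = -900
    grow_initial_increment: int = 64
    grow_max_threshold: int = 0
    # lungs
    lung_threshold_hu: float = -300.0
    lung_min_area_mm2: float = 200.0
    propagation_neighborhood: int = 7
    include_pathology: bool = True
    # spine
    bone_threshold_hu: float = 145.0
    bone_min_area_mm2: float = 25.0
    bone_min_border_distance_px: float = 10.0
    vertebra_recovery_min_hu: float = 100.0
    fuzzy: FuzzyParams = field(default_factory=FuzzyParams)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    """Combined label volume plus per-stage diagnostics."""

    labels: LabelVolume
    stage_voxels: dict[str, int] = field(default_factory=dict)
    stage_errors: dict[str, str] = field(default_factory=dict)
    airway_trace: list | None = None
    canal_info: _spine.SpinalCanalResult | None = None


def run_pipeline(ct: CTVolume, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full segmentation and return the combined label map.

    Labels: 1 body, 2 right lung, 3 left lung, 4 trachea/main bronchi,
    5 bone, 6 spinal canal (0 background).
    """
    cfg = config or PipelineConfig()
    result = PipelineResult(
        labels=LabelVolume(
            labels=np.zeros(ct.shape, dtype=np.int16),
            spacing=ct.spacing,
            label_names=dict(LABELS),
        )
    )
    counts = result.stage_voxels

    # -- process 1: body -------------------------------------------------
    body = _body.segment_body(
        ct, hu_low=cfg.body_hu_low, hu_high=cfg.body_hu_high, min_area_mm2=cfg.body_min_area_mm2
    )
    counts["body"] = int(body.mask.sum())
    log.info("body: %d voxels", counts["body"])
    if counts["body"] == 0:
        log.warning("body stage produced an empty mask; downstream stages skipped")

    # -- process 2: lungs + airway --------------------------------------
    airway_mask = None
    lung_mask = None
    if counts["body"]:
        rough = _lungs.rough_lung_fields(ct, body, threshold_hu=cfg.lung_threshold_hu)
        counts["rough_lungs"] = int(rough.sum())
        try:
            seed = _airway.detect_trachea_seed(
                ct,
                body,
                n_top_slices=cfg.n_top_slices,
                air_hu=cfg.seed_air_hu,
                min_area_mm2=cfg.seed_min_area_mm2,
            )
            growth = _airway.adaptive_region_grow(
                ct,
                seed,
                initial_threshold=cfg.grow_initial_threshold,
                initial_increment=cfg.grow_initial_increment,
                max_threshold=cfg.grow_max_threshold,
            )
            result.airway_trace = growth.trace
            airway_mask = _airway.finalize_airway(growth.mask)
            counts["airway"] = int(airway_mask.mask.sum())
        except (_airway.SeedNotFoundError, ValueError, IndexError) as exc:
            result.stage_errors["airway"] = str(exc)
            log.warning("airway stage failed: %s", exc)

        if airway_mask is not None:
            lungs = _lungs.remove_airway_fill_close(rough, airway_mask)
        else:
            lungs = rough.copy()
        lungs = _lungs.correct_lung_fields(
            lungs, min_area_mm2=cfg.lung_min_area_mm2, pixel_area_mm2=ct.pixel_area_mm2
        )
        counts["corrected_lungs"] = int(lungs.sum())
        lung_mask = _lungs.separate_lungs(ct, lungs, body)
        if cfg.include_pathology:
            lung_mask = _lungs.include_pathology(
                lung_mask, neighborhood=cfg.propagation_neighborhood
            )
        counts["left_lung"] = int(lung_mask.left.sum())
        counts["right_lung"] = int(lung_mask.right.sum())

    # -- process 3: spine ------------------------------------------------
    bone = None
    canal = None
    if counts["body"]:
        bone = _spine.segment_bone(
            ct,
            body,
            threshold_hu=cfg.bone_threshold_hu,
            min_area_mm2=cfg.bone_min_area_mm2,
            min_border_distance_px=cfg.bone_min_border_distance_px,
        )
        counts["bone"] = int(bone.sum())
        vertebra = _spine.segment_vertebra(
            bone, body, ct, recovery_min_hu=cfg.vertebra_recovery_min_hu
        )
        counts["vertebra"] = int(vertebra.mask.sum())
        try:
            canal_result = _spine.segment_spinal_canal(ct, vertebra, params=cfg.fuzzy)
            result.canal_info = canal_result
            canal = canal_result.mask
            counts["spinal_canal"] = int(canal.sum())
        except RuntimeError as exc:
            result.stage_errors["spinal_canal"] = str(exc)
            log.warning("spinal canal stage failed: %s", exc)

    # -- compose label volume -------------------------------------------
    labels = result.labels.labels
    if counts["body"]:
        labels[body.mask] = LABEL_IDS["body"]
    if lung_mask is not None:
        labels[lung_mask.right] = LABEL_IDS["right_lung"]
        labels[lung_mask.left] = LABEL_IDS["left_lung"]
    if airway_mask is not None:
        labels[airway_mask.mask] = LABEL_IDS["trachea_bronchi"]
    if bone is not None:
        labels[bone] = LABEL_IDS["bone"]
    if canal is not None:
        labels[canal] = LABEL_IDS["spinal_canal"]
    return result
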