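"""Lung-field extraction, separation, and pathological-area inclusion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thoraxseg.airway import AirwayMask
from thoraxseg.body import BodyMask, segment_body
from thoraxseg.lungs import (
    LungMask,
    correct_lung_fields,
    include_pathology,
    interpolate_lungs,
    junction_roi,
    propagate_lung,
    remove_airway_fill_close,
    rough_lung_fields,
    separate_lungs,
)
from thoraxseg.metrics import volume_overlap_ratio
from thoraxseg.volume import CTVolume

from conftest import random_blob_mask


def test_rough_fields_threshold_and_body_restriction():
    data = np.full((1, 8, 8), 30.0)
    data[0, 2, 2] = -850.0  # lung density inside body
    data[0, 2, 3] = -100.0  # too dense
    data[0, 0, 0] = -850.0  # will be outside the body mask
    ct = CTVolume(data=data, spacing=(2.5, 1.0, 1.0))
    body = np.zeros((1, 8, 8), dtype=bool)
    body[0, 1:7, 1:7] = True
    rough = rough_lung_fields(ct, BodyMask(mask=body))
    assert rough[0, 2, 2]
    assert not rough[0, 2, 3]
    assert not rough[0, 0, 0]


def test_rough_fields_cover_lungs_and_lumen(clean_phantom):
    ct, truth = clean_phantom
    rough = rough_lung_fields(ct, segment_body(ct))
    assert (truth.lungs & ~rough).mean() < 0.001
    assert (truth.lumen & ~rough).sum() == 0


def _airway(mask):
    return AirwayMask(mask=mask, lumen=mask)


def test_remove_airway_exact_cancellation():
    m = np.zeros((2, 10, 10), dtype=bool)
    m[0, 3:6, 3:6] = True
    assert not remove_airway_fill_close(m.copy(), _airway(m)).any()


def test_vessel_hole_filled():
    m = np.zeros((1, 20, 20), dtype=bool)
    m[0, 2:18, 2:18] = True
    m[0, 8:10, 8:11] = False  # interior 6-px vessel hole
    out = remove_airway_fill_close(m, _airway(np.zeros_like(m)))
    assert out[0, 8:10, 8:11].all()


def test_correction_removes_small_and_disconnected_regions():
    m = np.zeros((9, 32, 32), dtype=bool)
    m[2:7, 4:20, 4:20] = True  # main lung block through the central slice
    # caudal disconnected bowel-gas-like blob, large enough (256 mm^2) to
    # survive the area filter: only 3D connectivity can remove it
    m[8, 8:24, 8:24] = True
    out = correct_lung_fields(m, min_area_mm2=200, pixel_area_mm2=1.0)
    assert not out[8].any()  # bowel-gas-like blob removed
    assert out[2:7, 4:20, 4:20].all()
    # never adds voxels
    assert not (out & ~m).any()


def test_correction_small_area_rule():
    # an isolated 100 mm^2 region is eliminated, 300 mm^2 stays (if connected
    # to the central slice)
    m = np.zeros((3, 40, 40), dtype=bool)
    m[1, 5:15, 5:15] = True  # 100 px at 2 mm^2/px -> 200 mm^2 boundary case
    out = correct_lung_fields(m, min_area_mm2=200, pixel_area_mm2=1.0)
    assert not out.any()  # 100 mm^2 < 200 -> gone
    out2 = correct_lung_fields(m, min_area_mm2=200, pixel_area_mm2=3.0)
    assert out2.sum() == 100  # 300 mm^2 kept


def test_correction_idempotent_on_clean_connected_input():
    m = np.zeros((5, 20, 20), dtype=bool)
    m[:, 2:18, 2:18] = True
    out = correct_lung_fields(m, pixel_area_mm2=4.0)
    assert (out == m).all()


def test_junction_roi_arithmetic():
    roi = junction_roi((50, 350, 100, 400))
    assert (roi.left, roi.right, roi.top, roi.bottom) == (200, 300, 50, 200)


@given(
    top=st.integers(0, 100),
    height=st.integers(2, 200),
    left=st.integers(0, 100),
    width=st.integers(3, 300),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_junction_roi_invariants(top, height, left, width):
    roi = junction_roi((top, top + height, left, left + width))
    assert left <= roi.left < roi.right <= left + width
    assert top <= roi.top < roi.bottom <= top + height


def test_disjoint_lungs_do_not_trigger_separation(clean_phantom):
    ct, truth = clean_phantom
    body = segment_body(ct)
    lungs = truth.left_lung | truth.right_lung
    lm = separate_lungs(ct, lungs, body)
    # nothing removed, assignment by centroid matches the truth sides
    assert (lm.combined == lungs).all()
    assert (lm.right == truth.right_lung).all()
    assert (lm.left == truth.left_lung).all()


def test_fused_lungs_are_separated(fused_phantom, fused_result):
    _, truth = fused_phantom
    L = fused_result.labels
    right, left = L.mask("right_lung"), L.mask("left_lung")
    assert not (right & left).any()
    assert volume_overlap_ratio(right, truth.right_lung) >= 98.0
    assert volume_overlap_ratio(left, truth.left_lung) >= 98.0


def test_interpolation_semantics_and_fixed_point(rng):
    m = np.zeros((10, 4, 4), dtype=bool)
    m[3, 1, 1] = True
    m[7, 1, 1] = True
    out = interpolate_lungs(m)
    assert out[3:8, 1, 1].all()
    assert out.sum() == 5
    # single-slice pixels unchanged
    single = np.zeros((5, 3, 3), dtype=bool)
    single[2, 1, 1] = True
    assert (interpolate_lungs(single) == single).all()
    # idempotence on random masks
    for _ in range(5):
        m = random_blob_mask(rng, (12, 16, 16), p=0.7)
        once = interpolate_lungs(m)
        assert (interpolate_lungs(once) == once).all()


def brute_propagation_step(lung, m=7):
    """Independent single-iteration oracle for the propagation rule."""
    lung = np.asarray(lung, dtype=bool)
    nz, ny, nx = lung.shape
    out = lung.copy()
    h = m // 2
    # border pixels: lung pixels with a non-lung (or out-of-slice) in-plane
    # 8-neighbourhood? candidates are non-lung pixels within the in-slice
    # m x m window of any lung pixel (equivalent formulation)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if lung[z, y, x]:
                    continue
                window = lung[z, max(y - h, 0) : y + h + 1, max(x - h, 0) : x + h + 1]
                if not window.any():
                    continue
                block = lung[
                    max(z - h, 0) : z + h + 1,
                    max(y - h, 0) : y + h + 1,
                    max(x - h, 0) : x + h + 1,
                ]
                if block.sum() > (m ** 3) // 2:
                    out[z, y, x] = True
    return out


def test_propagation_majority_threshold_is_strict():
    """A candidate with exactly 172 of 343 lung neighbours is admitted,
    with 171 it is not."""
    for count, admitted in ((172, True), (171, False)):
        lung = np.zeros((9, 13, 13), dtype=bool)
        cand = (4, 6, 6)
        # fill `count` voxels of the 7x7x7 window around cand, skipping cand
        # itself, starting in cand's slice so it is an in-slice candidate
        placed = 0
        for z in list(range(4, 8)) + list(range(1, 4)):
            for y in range(3, 10):
                for x in range(3, 10):
                    if (z, y, x) == cand or placed >= count:
                        continue
                    lung[z, y, x] = True
                    placed += 1
        assert placed == count
        out = propagate_lung(lung, max_iter=1)
        assert out[cand] == admitted


def test_propagation_matches_bruteforce_single_step(rng):
    for _ in range(4):
        m = random_blob_mask(rng, (14, 14, 14), p=0.45, smooth=2.0)
        ours = propagate_lung(m, max_iter=1)
        oracle = brute_propagation_step(m)
        assert (ours == oracle).all()


def test_propagation_fixed_point_on_solid_cube():
    m = np.zeros((15, 15, 15), dtype=bool)
    m[4:11, 4:11, 4:11] = True
    out = propagate_lung(m)
    assert (propagate_lung(out, max_iter=1) == out).all()


def test_include_pathology_set_algebra(rng):
    for _ in range(3):
        left = random_blob_mask(rng, (10, 14, 14), p=0.75, smooth=2.0)
        right = np.zeros_like(left)
        lm = include_pathology(LungMask(left=left, right=right))
        # output is a superset of the input
        assert not (left & ~lm.left).any()
        # additions lie in both the interpolated and the propagated masks
        adds = lm.left & ~left
        assert not (adds & ~interpolate_lungs(left)).any()
        assert not (adds & ~propagate_lung(left)).any()
        assert not lm.right.any()


def test_include_pathology_identity_when_stages_agree():
    m = np.zeros((6, 10, 10), dtype=bool)
    m[1:5, 2:8, 2:8] = True  # solid block: interpolation and propagation fixed
    lm = include_pathology(LungMask(left=np.zeros_like(m), right=m))
    assert (lm.right == m).all()


def test_pathology_inclusion_covers_tumors(tumor_phantoms):
    for name, d in tumor_phantoms.items():
        tum = d["truth"].tumor
        L = d["with"].labels
        lungs = L.mask("right_lung") | L.mask("left_lung")
        Ln = d["without"].labels
        lungs_no = Ln.mask("right_lung") | Ln.mask("left_lung")
        cov = (lungs & tum).sum() / tum.sum()
        cov_no = (lungs_no & tum).sum() / tum.sum()
        assert cov >= 0.95, name
        assert cov > cov_no, name
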