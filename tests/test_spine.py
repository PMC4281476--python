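"""Bone/vertebra segmentation, enclosure test and fuzzy canal segmentation."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from thoraxseg.body import BodyMask, segment_body
from thoraxseg.metrics import volume_overlap_ratio
from thoraxseg.spine import (
    CanalLostError,
    FuzzyParams,
    check_enclosed,
    fuzzy_canal_slice,
    segment_bone,
    segment_spinal_canal,
    segment_vertebra,
    _vertebra_roi,
)
from thoraxseg.volume import CTVolume

from conftest import random_blob_mask


def _body_full(shape):
    return BodyMask(mask=np.ones(shape, dtype=bool))


def test_bone_area_and_border_distance_rules():
    # 300 HU components: one deep inside (kept), one 5 px from the border
    # (rejected), one too small (rejected)
    data = np.full((1, 64, 64), 30.0)
    data[0, 28:34, 28:34] = 300.0  # 36 mm^2, centre: kept
    data[0, 3:9, 28:34] = 300.0  # 36 mm^2 but 3 px from border: rejected
    data[0, 50, 50] = 300.0  # 1 mm^2: rejected
    ct = CTVolume(data=data, spacing=(2.5, 1.0, 1.0))
    bone = segment_bone(ct, _body_full((1, 64, 64)))
    assert bone[0, 28:34, 28:34].all()
    assert not bone[0, 3:9, 28:34].any()
    assert not bone[0, 50, 50]


def test_vertebra_roi_arithmetic():
    # body bbox with CP=(256,256) and BB.bottom=450:
    # ROI rows 206..440, cols 246..266
    body_slice = np.zeros((512, 512), dtype=bool)
    body_slice[62:451, 100:413] = True
    top, bottom, left, right = _vertebra_roi(body_slice)
    assert (left, right) == (246, 266)
    assert (top, bottom) == (206, 440)


def test_vertebra_selection_excludes_sternum():
    # two bone segments; only the posterior one intersects the midline ROI
    data = np.full((1, 128, 128), 30.0)
    data[0, 30:36, 20:32] = 300.0  # lateral rib-like bone outside the ROI columns
    data[0, 80:100, 58:70] = 300.0  # posterior vertebra inside ROI
    ct = CTVolume(data=data, spacing=(2.5, 1.0, 1.0))
    body = np.zeros((1, 128, 128), dtype=bool)
    body[0, 4:124, 4:124] = True
    bone = segment_bone(ct, BodyMask(mask=body))
    assert bone[0, 30:36, 20:32].all() and bone[0, 80:100, 58:70].all()
    vert = segment_vertebra(bone, BodyMask(mask=body), ct)
    assert vert.mask[0, 80:100, 58:70].all()
    assert not vert.mask[0, 30:36, 20:32].any()


def test_vertebra_empty_bone_gives_empty_mask():
    data = np.full((1, 64, 64), 30.0)
    ct = CTVolume(data=data, spacing=(2.5, 1.0, 1.0))
    vert = segment_vertebra(
        np.zeros((1, 64, 64), dtype=bool), _body_full((1, 64, 64)), ct
    )
    assert not vert.mask.any()


def _ring(shape=(32, 32), center=(16, 16), outer=10, inner=5):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return (d2 <= outer ** 2) & (d2 > inner ** 2)


def test_enclosure_topology():
    ring = _ring()
    enclosed, region = check_enclosed(ring)
    assert enclosed
    rr, cc = np.ogrid[:32, :32]
    hole = ((rr - 16) ** 2 + (cc - 16) ** 2) <= 25
    assert (region == hole).all()
    # C-shaped ring: open
    open_ring = ring.copy()
    open_ring[16:, 14:19] = False
    enclosed, region = check_enclosed(open_ring)
    assert not enclosed and region is None
    # empty slice
    assert check_enclosed(np.zeros((8, 8), dtype=bool)) == (False, None)


def test_enclosure_returns_largest_hole():
    m = np.ones((20, 40), dtype=bool)
    m[8:11, 5:10] = False  # 15-px hole
    m[5:15, 20:30] = False  # 100-px hole
    enclosed, region = check_enclosed(m)
    assert enclosed
    assert region.sum() == 100 and region[10, 25]


def flood_from_border_oracle(mask):
    """Enclosure oracle: a slice is enclosed iff some non-bone pixel in the
    bbox is unreachable by a 4-connected flood from the bbox border."""
    rows = np.flatnonzero(mask.any(axis=1))
    if rows.size == 0:
        return False
    cols = np.flatnonzero(mask.any(axis=0))
    win = ~mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    labels, n = ndi.label(win)
    border = set(labels[0]) | set(labels[-1]) | set(labels[:, 0]) | set(labels[:, -1])
    inner = set(np.unique(labels[labels > 0])) - border
    return bool(inner)


def test_enclosure_agrees_with_flood_oracle(rng):
    for _ in range(50):
        m = random_blob_mask(rng, (18, 18), p=0.5, smooth=1.2)
        assert check_enclosed(m)[0] == flood_from_border_oracle(m)


# --- fuzzy segmentation -----------------------------------------------------

def test_prior_selection_range():
    p = FuzzyParams()
    assert p.prior_range == (-14.5, 60.5)


def test_membership_is_one_at_the_estimated_mean():
    # uniform 23 HU window: mu_SP = 23, sigma degenerate -> prior fallback;
    # membership at HU == mu_SP must be exactly 1 -> the whole disk survives
    data = np.full((40, 40), 300.0)
    rr, cc = np.ogrid[:40, :40]
    disk = (rr - 20) ** 2 + (cc - 20) ** 2 <= 16
    data[disk] = 23.0
    out = fuzzy_canal_slice(data, (20, 20))
    opened = ndi.binary_opening(disk, structure=np.ones((3, 3)))
    assert (out == opened).all()


def test_fuzzy_canal_lost_when_no_pixel_in_prior_range():
    data = np.full((30, 30), 300.0)
    with pytest.raises(CanalLostError):
        fuzzy_canal_slice(data, (15, 15))


def grayscale_reconstruction_oracle(marker, mask):
    """Iterated 8-connected geodesic dilation until stability."""
    out = marker.copy()
    footprint = np.ones((3, 3))
    while True:
        dilated = np.minimum(ndi.grey_dilation(out, footprint=footprint), mask)
        if np.array_equal(dilated, out):
            return out
        out = dilated


def test_reconstruction_matches_geodesic_dilation_oracle(rng):
    from skimage.morphology import reconstruction

    for _ in range(10):
        mask = rng.random((32, 32))
        marker = np.where(rng.random((32, 32)) < 0.05, mask, 0.0)
        rec = reconstruction(marker, mask, method="dilation")
        oracle = grayscale_reconstruction_oracle(marker, mask)
        assert np.allclose(rec, oracle)
        assert (rec <= mask + 1e-12).all()
        assert (rec >= marker - 1e-12).all()


def test_fuzzy_disk_against_reconstruction_oracle():
    """Noisy canal disk in bone: the fuzzy slice result equals the
    brute-force pipeline built on the geodesic-dilation oracle."""
    rng = np.random.default_rng(3)
    data = np.full((40, 40), 300.0)
    rr, cc = np.ogrid[:40, :40]
    disk = (rr - 20) ** 2 + (cc - 20) ** 2 <= 36
    data[disk] = 23.0
    data = data + rng.normal(0, 4, size=data.shape)
    out = fuzzy_canal_slice(data, (20, 20))

    window = data[15:26, 15:26]
    sel = (window >= -14.5) & (window <= 60.5)
    mu, sigma = window[sel].mean(), window[sel].std()
    membership = np.exp(-((data - mu) ** 2) / (2 * sigma ** 2))
    marker = np.zeros_like(membership)
    seeds = np.zeros_like(membership, dtype=bool)
    seeds[15:26, 15:26] = sel
    marker[seeds] = membership[seeds]
    rec = grayscale_reconstruction_oracle(marker, membership)
    binar = rec >= 0.5
    labels, n = ndi.label(binar, structure=np.ones((3, 3)))
    counts = np.bincount(labels.ravel())[1:]
    largest = labels == (int(np.argmax(counts)) + 1)
    expected = ndi.binary_opening(largest, structure=np.ones((3, 3)))
    assert (out == expected).all()


def test_canal_from_enclosed_slices_without_fuzzy(clean_phantom, clean_result):
    _, truth = clean_phantom
    info = clean_result.canal_info
    assert info.fuzzy_calls == 0
    assert all(s == "enclosed" for s in info.slice_source)
    assert not (info.mask & truth.bone).any()


def test_open_ring_recovered_by_fuzzy_propagation(open_ring_phantom, open_ring_result):
    _, truth = open_ring_phantom
    info = open_ring_result.canal_info
    assert info.fuzzy_calls == 3
    assert [s for s in info.slice_source[:3]] == ["fuzzy"] * 3
    assert all(s == "enclosed" for s in info.slice_source[3:])
    assert volume_overlap_ratio(info.mask, truth.canal) >= 95.0
    assert not (info.mask & truth.bone).any()


def test_canal_requires_an_enclosed_slice():
    # open rings everywhere -> cannot initialize
    data = np.full((3, 32, 32), 30.0)
    ring = _ring()
    ring[16:, 14:19] = False
    for k in range(3):
        data[k][ring] = 300.0
    ct = CTVolume(data=data, spacing=(2.5, 1.0, 1.0))
    from thoraxseg.spine import VertebraMask

    vert = VertebraMask(mask=np.broadcast_to(ring, (3, 32, 32)).copy())
    with pytest.raises(RuntimeError):
        segment_spinal_canal(ct, vert)
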