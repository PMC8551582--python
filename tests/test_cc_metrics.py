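"""Choriocapillaris stage: large-vessel masking and flow-void particles."""

import numpy as np
import pytest

from octaquant.cc_metrics import (
    cc_binarize_masked,
    flow_void_metrics,
    large_vessel_mask,
)
from octaquant.roi_geometry import RegionMask, macular_mask
from octaquant.slab_io import EnfaceSlab, Layer
from octaquant.synthetic_data import CcFieldSpec, generate_cc, random_lesions
from octaquant.thresholding import BinaryMap, isodata_binarize, phansalkar_binarize

PIXEL_UM2 = 18.0 * 18.0  # 324 um^2 at the default widefield pitch


def full_region(shape, pixel_area_mm2=PIXEL_UM2 / 1e6):
    return RegionMask("full", np.ones(shape, bool), pixel_area_mm2)


def planted_artery_slab(rng, width_um=50.0):
    """Dim capillary texture + one bright horizontal artery band."""
    img = np.full((500, 834), 25.0)
    img += rng.normal(0, 5, img.shape)
    caps = rng.random(img.shape) < 0.45
    img[caps] = 60.0 + rng.normal(0, 5, caps.sum())
    artery = np.zeros(img.shape, bool)
    half_px = width_um / 2 / 18.0
    rows = np.abs(np.arange(500) - 250 + 0.0) <= half_px
    artery[rows] = True
    img[artery] = 245.0
    slab = EnfaceSlab(np.clip(img, 0, 255).astype(np.uint8), Layer.SVP)
    return slab, artery


class TestLargeVesselMask:
    def test_planted_artery_recovered(self, rng):
        slab, artery = planted_artery_slab(rng)
        lv = large_vessel_mask(slab)
        assert (lv.mask & artery).sum() >= 0.9 * artery.sum()
        background = ~artery
        assert (lv.mask & background).sum() < 0.02 * background.sum()

    def test_blank_slab_empty_mask(self):
        slab = EnfaceSlab(np.zeros((500, 834), np.uint8), Layer.SVP)
        assert not large_vessel_mask(slab).mask.any()

    def test_zero_cutoff_equals_plain_threshold(self, rng):
        slab, _ = planted_artery_slab(rng)
        lv = large_vessel_mask(slab, min_component_area_um2=0.0)
        assert np.array_equal(lv.mask, isodata_binarize(slab).mask)

    def test_components_respect_cutoff(self, rng):
        from scipy import ndimage

        slab, _ = planted_artery_slab(rng)
        cutoff = 5000.0
        lv = large_vessel_mask(slab, min_component_area_um2=cutoff)
        labels, n = ndimage.label(lv.mask, structure=np.ones((3, 3)))
        counts = np.bincount(labels.ravel())[1:]
        assert (counts * slab.pixel_area_um2 >= cutoff).all()


class TestCcBinarizeMasked:
    def test_empty_lv_mask_identity(self, rng):
        cc, _ = generate_cc(CcFieldSpec(seed=5))
        roi = macular_mask(cc, (250, 417))
        binary, analyzed = cc_binarize_masked(cc, None, roi)
        assert np.array_equal(analyzed.mask, roi.mask)
        assert np.array_equal(binary.mask, phansalkar_binarize(cc).mask)

    def test_lv_covering_roi_errors(self, rng):
        cc, _ = generate_cc(CcFieldSpec(seed=5))
        roi = macular_mask(cc, (250, 417))
        from octaquant.cc_metrics import LargeVesselMask

        lv = LargeVesselMask(np.ones(cc.shape, bool), "x", 0.0)
        with pytest.raises(ValueError):
            cc_binarize_masked(cc, lv, roi)

    def test_masking_projection_artifact_raises_cc_vpd(self):
        """Shadow under a large vessel darkens the CC; excluding those pixels
        from the analyzed region must increase measured CC perfusion."""
        # stripes narrower than the Phansalkar window, like real vessels:
        # the local threshold cannot adapt inside them, so they read as voids
        shadow = np.zeros((500, 834), bool)
        for c in range(150, 700, 60):
            shadow[:, c : c + 6] = True
        cc, _ = generate_cc(
            CcFieldSpec(seed=9, projection_mask=shadow, projection_contrast=0.5)
        )
        roi = macular_mask(cc, (250, 417))
        from octaquant.cc_metrics import LargeVesselMask
        from octaquant.retina_metrics import vpd

        lv = LargeVesselMask(shadow, "syn", 0.0)
        b_plain, a_plain = cc_binarize_masked(cc, None, roi)
        b_masked, a_masked = cc_binarize_masked(cc, lv, roi)
        assert vpd(b_masked, a_masked) > vpd(b_plain, a_plain)


def plant_disks(shape, disks):
    """disks: list of (row, col, area_um2). Returns boolean void map."""
    void = np.zeros(shape, bool)
    rr, cc_ = np.mgrid[: shape[0], : shape[1]]
    for r0, c0, area in disks:
        rad_px = np.sqrt(area / np.pi) / 18.0
        void |= (rr - r0) ** 2 + (cc_ - c0) ** 2 < rad_px**2
    return void


class TestFlowVoidMetrics:
    def test_fully_perfused(self):
        shape = (500, 834)
        binary = BinaryMap(np.ones(shape, bool), "phansalkar")
        m = flow_void_metrics(binary, full_region(shape), PIXEL_UM2)
        assert m.void_area_percent == 0.0
        assert m.fv1000_count == 0
        assert np.isnan(m.fv1000_mean_area_um2)

    def test_planted_disks_counts_and_sizes(self):
        """Five 2000 um^2 voids count toward FV1,000; ten 500 um^2 do not."""
        shape = (500, 834)
        big = [(100 + 40 * i, 150, 2000.0) for i in range(5)]
        small = [(100 + 35 * i, 500, 500.0) for i in range(10)]
        void = plant_disks(shape, big + small)
        binary = BinaryMap(~void, "phansalkar")
        m = flow_void_metrics(binary, full_region(shape), PIXEL_UM2)
        assert m.fv1000_count == 5
        assert m.fv1000_mean_area_um2 == pytest.approx(2000.0, rel=0.25)  # one px ring
        total_planted = void.sum() * PIXEL_UM2
        analyzed = shape[0] * shape[1] * PIXEL_UM2
        assert m.void_area_percent == pytest.approx(100 * total_planted / analyzed)

    def test_merging_subthreshold_voids_crosses_cutoff(self):
        # two ~600 um^2 blobs (2 px = 648 um^2 each at 18 um/px): separate
        # they stay below the 1,000 um^2 cutoff, merged they exceed it
        shape = (500, 834)
        apart = np.zeros(shape, bool)
        apart[100, 100:102] = True
        apart[100, 120:122] = True
        m_apart = flow_void_metrics(
            BinaryMap(~apart, "x"), full_region(shape), PIXEL_UM2
        )
        assert m_apart.fv1000_count == 0
        touching = np.zeros(shape, bool)
        touching[100, 100:104] = True  # merged 4 px = 1296 um^2
        m_touch = flow_void_metrics(
            BinaryMap(~touching, "x"), full_region(shape), PIXEL_UM2
        )
        assert m_touch.fv1000_count == 1
        assert m_touch.fv1000_mean_area_um2 > 1000.0

    def test_adding_isolated_component_increments_count(self):
        shape = (500, 834)
        base = plant_disks(shape, [(100, 100, 3000.0)])
        extra = plant_disks(shape, [(300, 600, 2000.0)])
        m1 = flow_void_metrics(BinaryMap(~base, "x"), full_region(shape), PIXEL_UM2)
        m2 = flow_void_metrics(
            BinaryMap(~(base | extra), "x"), full_region(shape), PIXEL_UM2
        )
        assert m2.fv1000_count == m1.fv1000_count + 1
        added = extra.sum() * PIXEL_UM2
        assert m2.voids.total_void_area_um2 == pytest.approx(
            m1.voids.total_void_area_um2 + added
        )

    def test_mean_times_count_bounded_by_total(self, rng):
        cc, _ = generate_cc(
            CcFieldSpec(seed=3, lesions=random_lesions(rng, 20))
        )
        binary = phansalkar_binarize(cc)
        m = flow_void_metrics(binary, full_region(cc.shape), cc.pixel_area_um2)
        assert m.fv1000_mean_area_um2 * m.fv1000_count <= m.voids.total_void_area_um2 + 1e-6

    def test_empty_region_errors(self):
        shape = (500, 834)
        binary = BinaryMap(np.ones(shape, bool), "x")
        empty = RegionMask("none", np.zeros(shape, bool), PIXEL_UM2 / 1e6)
        with pytest.raises(ValueError):
            flow_void_metrics(binary, empty, PIXEL_UM2)


def test_complementarity_void_plus_vpd_is_100(rng):
    """CC void-area percent and CC-VPD percent are exact complements when
    computed over the same analyzed region and binarization."""
    from octaquant.retina_metrics import vpd

    cc, _ = generate_cc(CcFieldSpec(seed=21, lesions=random_lesions(rng, 25)))
    binary = phansalkar_binarize(cc)
    roi = macular_mask(cc, (250, 417))
    m = flow_void_metrics(binary, roi, cc.pixel_area_um2)
    assert m.void_area_percent + 100.0 * vpd(binary, roi) == pytest.approx(100.0, abs=1e-9)
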