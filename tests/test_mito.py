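"""Perinuclear ROIs, MitoUnit, fragmentation, TMRE/MitoSOX quantification."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

from mitoflux import (
    MitoObject,
    SimConfig,
    WellImage,
    WellSpec,
    build_cell_rois,
    classify_fragmentation,
    detect_mito_objects,
    quantify_membrane_potential,
    quantify_mito_content,
    quantify_mtros,
    render_well_image,
    segment_nuclei,
)
from mitoflux.simulate import Noise

PX = 0.65


def single_nucleus_image(center=(128, 128), radius_um=5.0, shape=(256, 256),
                         extra_channels=None):
    """One bright round nucleus on flat background, plus optional channels."""
    chan = np.full(shape, 100.0)
    rr, cc = draw_disk(center, radius_um / PX, shape=shape)
    chan[rr, cc] += 3000.0
    channels = {"nuclear": ndi.gaussian_filter(chan, 0.8)}
    if extra_channels:
        channels.update(extra_channels)
    return WellImage("C5", channels, PX)


class TestCellROIs:
    def test_isolated_nucleus_roi_is_annulus(self):
        img = single_nucleus_image()
        seg = segment_nuclei(img)
        assert len(seg) == 1
        rois = build_cell_rois(seg, img, max_distance_um=10.0)
        r = np.sqrt(seg.records[0].area_um2 / np.pi)
        expected = np.pi * ((r + 10.0) ** 2 - r ** 2)
        assert rois.area_um2(1) == pytest.approx(expected, rel=0.03)

    def test_two_distant_nuclei_disjoint_full_annuli(self):
        chan = np.full((256, 256), 100.0)
        for c in ((128, 80), (128, 80 + 40.0 / PX)):   # 40 um apart
            rr, cc = draw_disk(c, 5.0 / PX, shape=chan.shape)
            chan[rr, cc] += 3000.0
        img = WellImage("C5", {"nuclear": ndi.gaussian_filter(chan, 0.8)}, PX)
        seg = segment_nuclei(img)
        assert len(seg) == 2
        rois = build_cell_rois(seg, img)
        assert not np.any(rois.mask(1) & rois.mask(2))
        a1, a2 = rois.area_um2(1), rois.area_um2(2)
        r = np.sqrt(seg.records[0].area_um2 / np.pi)
        expected = np.pi * ((r + 10.0) ** 2 - r ** 2)
        assert a1 == pytest.approx(expected, rel=0.03)
        assert a2 == pytest.approx(expected, rel=0.03)

    def test_zero_distance_gives_empty_rois(self, std_well, std_segmentation):
        _, _, img, _ = std_well
        rois = build_cell_rois(std_segmentation, img, max_distance_um=0.0)
        assert not rois.union().any()

    def test_roi_pixels_within_distance_of_own_nucleus(self, std_well, std_rois):
        """Pixelwise: every ROI pixel is within 10 µm of its own nucleus and
        not nearer to any other nucleus."""
        rois = std_rois
        outside = rois.nucleus_labels == 0
        dist, (ir, ic) = ndi.distance_transform_edt(outside, return_indices=True)
        nearest = rois.nucleus_labels[ir, ic]
        roi = rois.roi_labels > 0
        assert np.all(dist[roi] * rois.pixel_size_um <= rois.max_distance_um + 1e-9)
        assert np.array_equal(rois.roi_labels[roi], nearest[roi])
        # ROIs exclude nuclei
        assert not np.any(roi & (rois.nucleus_labels > 0))


class TestMitoContent:
    def test_blank_channel_zero_mitounit(self):
        img = single_nucleus_image(extra_channels={"mito": np.zeros((256, 256))})
        seg = segment_nuclei(img)
        rois = build_cell_rois(seg, img)
        mq = quantify_mito_content(img, rois)
        assert mq.well_mitounit == 0.0

    def test_missing_channel_flagged(self, std_well, std_rois):
        _, _, img, _ = std_well
        bare = WellImage(img.well_id, {"nuclear": img.channel("nuclear")},
                         img.pixel_size_um, img.well_center_px, img.well_radius_px)
        with pytest.warns(UserWarning, match="mito channel missing"):
            mq = quantify_mito_content(bare, std_rois)
        assert "missing_channel" in mq.flags

    def test_well_mitounit_matches_truth_sum(self, noise_off_well, noise_off_rois):
        _, _, img, truth = noise_off_well
        mq = quantify_mito_content(img, noise_off_rois)
        expected = sum(o["intensity"] for o in truth["mito_objects"])
        assert mq.well_mitounit == pytest.approx(expected, rel=0.05)

    def test_mitounit_additive_over_cells(self):
        """MitoUnit of a two-cell image equals the sum of the single-cell
        images' values (noise off)."""

        def build(cells):
            nuc = np.full((256, 256), 100.0)
            mit = np.full((256, 256), 50.0)
            for cy, cx in cells:
                rr, cc = draw_disk((cy, cx), 5.0 / PX, shape=nuc.shape)
                nuc[rr, cc] += 3000.0
                rr, cc = draw_disk((cy, cx + 10.0 / PX), 1.5, shape=mit.shape)
                mit[rr, cc] += 2000.0
            img = WellImage("C5", {"nuclear": ndi.gaussian_filter(nuc, 0.8),
                                   "mito": ndi.gaussian_filter(mit, 0.5)}, PX)
            seg = segment_nuclei(img)
            rois = build_cell_rois(seg, img)
            return quantify_mito_content(img, rois, background=50.0).well_mitounit

        a = build([(90, 90)])
        b = build([(170, 170)])
        both = build([(90, 90), (170, 170)])
        assert both == pytest.approx(a + b, rel=0.01)

    def test_depleted_well_flagged_non_respiring(self):
        spec = WellSpec("C4", n_cells=10000, mito_per_cell=500.0,
                        per_cell_ocr=1e-4, tmre_factor=0.05)
        cfg = SimConfig(seed=6, wells=[spec], image_size_px=(512, 512),
                        field_fraction=0.004, noise=Noise())
        img, _ = render_well_image(spec, cfg)
        seg = segment_nuclei(img)
        rois = build_cell_rois(seg, img)
        mq = quantify_mito_content(img, rois)
        assert "non_respiring" in mq.flags

    def test_healthy_well_not_flagged(self, std_well, std_rois):
        _, _, img, _ = std_well
        mq = quantify_mito_content(img, std_rois)
        assert "non_respiring" not in mq.flags
        assert mq.unassigned_fraction < 0.25


def bar_image(length_um=10.0, width_um=0.6, shape=(256, 256), y_offset_um=8.0):
    """A single tubule-like bar in the ROI of one nucleus."""
    mit = np.full(shape, 50.0)
    y0, x0 = 128 + int(y_offset_um / PX), 128 - length_um / PX / 2
    n = int(length_um / PX * 2)
    for t in np.linspace(0, 1, n):
        rr, cc = draw_disk((y0, x0 + t * length_um / PX), width_um / 2 / PX + 0.45,
                           shape=shape)
        mit[rr, cc] = 2050.0
    return ndi.gaussian_filter(mit, 0.4)


def spot_image(centers, shape=(256, 256)):
    mit = np.full(shape, 50.0)
    for cy, cx in centers:
        rr, cc = draw_disk((cy, cx), 0.4 / PX + 0.35, shape=shape)
        mit[rr, cc] = 4050.0
    return ndi.gaussian_filter(mit, 0.4)


class TestMitoObjects:
    def seg_and_rois(self, mito_channel):
        img = single_nucleus_image(extra_channels={"mito": mito_channel})
        seg = segment_nuclei(img)
        rois = build_cell_rois(seg, img)
        return img, rois

    def test_single_punctum_round(self):
        cy = 128 + int(8.0 / PX)
        img, rois = self.seg_and_rois(spot_image([(cy, 128)]))
        objs = detect_mito_objects(img, rois)
        assert len(objs) == 1
        assert objs[0].form_factor >= 0.7
        assert objs[0].parent_nucleus_id == 1

    def test_single_tubule_elongated(self):
        img, rois = self.seg_and_rois(bar_image())
        objs = detect_mito_objects(img, rois)
        assert len(objs) == 1
        assert objs[0].form_factor <= 0.4
        assert objs[0].area_um2 == pytest.approx(0.6 * 10.0, rel=0.8)

    def test_blank_channel_no_objects(self):
        img, rois = self.seg_and_rois(np.full((256, 256), 50.0))
        assert detect_mito_objects(img, rois) == []

    def test_noise_only_channel_no_objects(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(50.0, 5.0, (256, 256)).clip(0)
        img, rois = self.seg_and_rois(noise)
        assert detect_mito_objects(img, rois) == []


class TestFragmentationClassification:
    def test_all_puncta_like_fraction_one(self):
        objs = [MitoObject(i, 1, area_um2=0.8, form_factor=0.9, mean_intensity=1.0)
                for i in range(5)]
        res = classify_fragmentation(objs)
        assert res.fragmentation_fraction == 1.0
        assert all(o.cls == "fragmented" for o in objs)

    def test_mixed_constructed_fixture_counts(self):
        """Three puncta plus one tubule in one ROI: counts (3, 1), 0.75."""
        cy = 128 + int(8.0 / PX)
        mit = np.maximum(spot_image([(cy, 110), (cy, 128), (cy, 146)]),
                         bar_image(length_um=8.0, y_offset_um=-8.0))
        img = single_nucleus_image(extra_channels={"mito": mit})
        seg = segment_nuclei(img)
        rois = build_cell_rois(seg, img)
        objs = detect_mito_objects(img, rois)
        res = classify_fragmentation(objs)
        assert (res.n_fragmented, res.n_granulated) == (3, 1)
        assert res.fragmentation_fraction == pytest.approx(0.75)

    def test_no_objects_fraction_absent(self):
        res = classify_fragmentation([])
        assert res.fragmentation_fraction is None

    def test_area_threshold_monotone(self, std_well, std_rois):
        """Raising the area threshold never decreases n_fragmented."""
        _, _, img, _ = std_well
        objs = detect_mito_objects(img, std_rois)
        counts = [classify_fragmentation(objs, max_area_um2=a).n_fragmented
                  for a in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert counts == sorted(counts)

    def test_estimates_track_truth_ordering(self):
        """Wells at frag_prob 0.2 vs 0.8: fractions ordered and each within
        ±0.1 of the object-level truth proportion."""
        results = {}
        for fp in (0.2, 0.8):
            spec = WellSpec("C4", n_cells=10000, frag_prob=fp)
            cfg = SimConfig(seed=5, wells=[spec], image_size_px=(512, 512),
                            field_fraction=0.004, noise=Noise())
            img, truth = render_well_image(spec, cfg)
            seg = segment_nuclei(img)
            rois = build_cell_rois(seg, img)
            objs = detect_mito_objects(img, rois)
            est = classify_fragmentation(objs).fragmentation_fraction
            tru = np.mean([o["cls"] == "puncta" for o in truth["mito_objects"]])
            results[fp] = (est, tru)
        assert results[0.2][0] < results[0.8][0]
        for est, tru in results.values():
            assert est == pytest.approx(tru, abs=0.1)


class TestDyeChannels:
    def test_uniform_channel_mean_is_v_minus_b(self):
        img = single_nucleus_image(
            extra_channels={"tmre": np.full((256, 256), 700.0)}
        )
        seg = segment_nuclei(img)
        rois = build_cell_rois(seg, img)
        q = quantify_membrane_potential(img, rois, background=150.0)
        assert q.per_cell[1] == pytest.approx(700.0 - 150.0)

    def test_blank_channel_zero(self):
        img = single_nucleus_image(extra_channels={"tmre": np.zeros((256, 256))})
        seg = segment_nuclei(img)
        rois = build_cell_rois(seg, img)
        assert quantify_membrane_potential(img, rois).well_mean == 0.0

    def test_constant_offset_invariance(self, std_well, std_rois):
        """Adding a constant to the channel leaves background-subtracted
        per-cell means unchanged."""
        _, _, img, _ = std_well
        q0 = quantify_membrane_potential(img, std_rois)
        shifted = WellImage(
            img.well_id,
            {**img.channels, "tmre": img.channel("tmre") + 500.0},
            img.pixel_size_um, img.well_center_px, img.well_radius_px,
        )
        q1 = quantify_membrane_potential(shifted, std_rois)
        assert q1.well_mean == pytest.approx(q0.well_mean, rel=0.02, abs=2.0)

    def test_tmre_factor_ratio_recovered(self):
        """Condition factors 1.0 vs 0.2 give a ~5x well-mean ratio."""
        means = {}
        for tf in (1.0, 0.2):
            spec = WellSpec("C4", n_cells=10000, tmre_factor=tf)
            cfg = SimConfig(seed=17, wells=[spec], image_size_px=(512, 512),
                            field_fraction=0.004, noise=Noise())
            img, _ = render_well_image(spec, cfg)
            seg = segment_nuclei(img)
            rois = build_cell_rois(seg, img)
            means[tf] = quantify_membrane_potential(img, rois).well_mean
        assert means[1.0] / means[0.2] == pytest.approx(5.0, rel=0.2)

    def test_mitosox_doubling_recovered(self):
        means = {}
        for sf in (1.0, 2.0):
            spec = WellSpec("C4", n_cells=10000, mitosox_factor=sf)
            cfg = SimConfig(seed=19, wells=[spec], image_size_px=(512, 512),
                            field_fraction=0.004, noise=Noise())
            img, _ = render_well_image(spec, cfg)
            seg = segment_nuclei(img)
            rois = build_cell_rois(seg, img)
            means[sf] = quantify_mtros(img, rois).well_mean
        assert means[2.0] / means[1.0] == pytest.approx(2.0, rel=0.2)

    def test_mitosox_reports_quartiles(self, std_well, std_rois):
        _, _, img, _ = std_well
        q = quantify_mtros(img, std_rois)
        assert q.quartiles is not None
        q25, q50, q75 = q.quartiles
        assert q25 <= q50 <= q75
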