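import numpy as np
import pytest

from lymphmorph import segmentation as seg
from lymphmorph import synthetic as syn

from conftest import ring_mask


def arc_contour(radius, gap_deg, center=(0.0, 0.0), n=200):
    """Open circular arc (μm) missing ``gap_deg`` degrees of wall."""
    span = 2 * np.pi - np.deg2rad(gap_deg)
    th = np.linspace(0, span, n)
    return np.stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)], axis=1
    )


class TestSeparateStain:
    def test_recall_on_rendered_core(self, rendered_core):
        """Wall pixels of the rendered fixture are recovered with high recall."""
        image = rendered_core["image"]
        stain = seg.separate_stain(image, rendered_core["pixel_size"])
        # ground-truth wall pixels: re-render without noise and classify
        clean, _, _ = syn.render_core_image(
            rendered_core["vessels"], pixel_size=0.5, rng_seed=1234, noise_sigma=0.0
        )
        wall_truth = np.all(clean == np.array(syn.STAIN_RGB, np.uint8), axis=-1)
        recall = (stain.mask & wall_truth).sum() / wall_truth.sum()
        assert recall >= 0.95

    def test_all_background_non_evaluable(self):
        image = np.full((50, 50, 3), 250, np.uint8)
        stain = seg.separate_stain(image, 0.5)
        assert not stain.evaluable
        assert stain.mask.sum() == 0

    def test_counterstain_only_is_evaluable_but_unstained(self):
        image = np.full((50, 50, 3), np.array(syn.TISSUE_RGB, np.uint8), np.uint8)
        stain = seg.separate_stain(image, 0.5)
        assert stain.evaluable
        assert stain.tissue_area > 0
        assert stain.mask.sum() == 0

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            seg.separate_stain(np.zeros((0, 0, 3), np.uint8), 0.5)


class TestCloseOpenOutlines:
    def test_closed_contour_unchanged(self):
        pts = arc_contour(10, gap_deg=0)
        out = seg.close_open_outlines([seg.Contour(pts, closed=True)], max_gap=5)
        assert len(out) == 1
        assert out[0].closed and not out[0].was_closed
        assert np.array_equal(out[0].points, pts)

    def test_c_shape_closed_by_chord(self):
        # 3 μm endpoint gap on a 10 μm-radius arc
        gap_deg = np.rad2deg(2 * np.arcsin(1.5 / 10))
        pts = arc_contour(10, gap_deg=gap_deg)
        out = seg.close_open_outlines([seg.Contour(pts, closed=False)], max_gap=5)
        assert len(out) == 1
        assert out[0].closed and out[0].was_closed

    def test_wide_gap_discarded(self):
        pts = arc_contour(20, gap_deg=90)  # chord ~28 μm
        out = seg.close_open_outlines([seg.Contour(pts, closed=False)], max_gap=5)
        assert out == []

    def test_two_arcs_merged_into_one_ring(self):
        th1 = np.linspace(0.05, np.pi - 0.05, 100)
        th2 = np.linspace(np.pi + 0.05, 2 * np.pi - 0.05, 100)
        c1 = seg.Contour(np.stack([10 * np.cos(th1), 10 * np.sin(th1)], 1), False)
        c2 = seg.Contour(np.stack([10 * np.cos(th2), 10 * np.sin(th2)], 1), False)
        out = seg.close_open_outlines([c1, c2], max_gap=3)
        assert len(out) == 1
        assert out[0].closed and out[0].was_closed
        assert len(out[0].points) == 200

    def test_idempotence(self):
        gap_deg = np.rad2deg(2 * np.arcsin(1.5 / 10))
        pts = arc_contour(10, gap_deg=gap_deg)
        once = seg.close_open_outlines([seg.Contour(pts, closed=False)], max_gap=5)
        twice = seg.close_open_outlines(once, max_gap=5)
        assert len(twice) == len(once) == 1
        assert np.array_equal(once[0].points, twice[0].points)

    def test_invalid_gap(self):
        with pytest.raises(ValueError):
            seg.close_open_outlines([], max_gap=0)


class TestExtractRegions:
    def _stain(self, mask, px=0.5):
        return seg.StainMask(
            mask=mask,
            tissue_mask=np.ones_like(mask),
            pixel_size=px,
            tissue_area=mask.size * px**2 / 1e6,
        )

    def test_single_ring_lumen(self):
        # outer Ø 30 μm, 3 μm wall at 0.5 μm/px: outer r 30 px, inner r 24 px
        mask = ring_mask((100, 100), (50, 50), 30, 24)
        regions = seg.extract_vessel_regions(self._stain(mask), max_gap=10)
        assert len(regions) == 1
        r = regions[0]
        assert not r.was_closed
        inner_disc_px = np.pi * 24**2
        assert r.lumen_mask.sum() == pytest.approx(inner_disc_px, rel=0.05)

    def test_oversize_ring_discarded(self):
        # lumen longest axis 250 μm: large collectors are not considered
        mask = ring_mask((600, 600), (300, 300), 260, 250)
        regions = seg.extract_vessel_regions(self._stain(mask, px=1.0), max_gap=10)
        assert regions == []

    def test_two_disjoint_rings(self):
        mask = ring_mask((200, 200), (50, 50), 25, 20) | ring_mask(
            (200, 200), (140, 140), 30, 24
        )
        regions = seg.extract_vessel_regions(self._stain(mask), max_gap=10)
        assert len(regions) == 2
        a, b = regions
        # lumens disjoint: bounding boxes do not overlap
        assert a.bbox_offset != b.bbox_offset

    def test_broken_ring_closed_and_flagged(self):
        mask = ring_mask((100, 100), (50, 50), 25, 20)
        mask[48:53, 69:] = False  # carve a ~2.5 μm break through the wall
        regions = seg.extract_vessel_regions(self._stain(mask), max_gap=10)
        assert len(regions) == 1
        assert regions[0].was_closed

    def test_lumens_simply_connected_and_in_range(self, segmented_core):
        from scipy import ndimage

        px = segmented_core["pixel_size"]
        for r in segmented_core["regions"]:
            _, n = ndimage.label(r.lumen_mask)
            assert n == 1
            filled = ndimage.binary_fill_holes(r.lumen_mask)
            assert filled.sum() == r.lumen_mask.sum()  # no holes in the lumen
            axis = seg._feret_px(r.lumen_mask) * px
            assert 5.0 - px <= axis <= 200.0 + px

    def test_recovery_on_noise_free_core(self):
        """With no noise, every vessel with a closable gap is recovered."""
        vessels = syn.sample_core_vessels(
            20, rng_seed=42, open_vessel_fraction=0.25, core_diameter=700.0
        )
        image, _, _ = syn.render_core_image(
            vessels, core_diameter=700.0, pixel_size=0.5, rng_seed=42, noise_sigma=0.0
        )
        stain = seg.separate_stain(image, 0.5)
        regions = seg.extract_vessel_regions(stain, max_gap=10)
        assert len(regions) >= 0.9 * len(vessels)
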