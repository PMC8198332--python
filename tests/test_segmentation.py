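"""Object identification, shape measurement, roundness filtering, propagation."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from follimetry import (BinaryMask, LabelMap, ShapeRecord,
                        derive_epithelium, filter_by_form_factor,
                        identify_primary_objects, mask_intraluminal_nuclei,
                        measure_shape, propagate_follicles, relate_objects)
from follimetry.segmentation import apply_label_overrides

from conftest import disc_mask


class TestIdentifyPrimaryObjects:
    def test_separated_discs_are_counted(self):
        mask = np.zeros((64, 64), bool)
        for c in [(10, 10), (10, 30), (10, 50), (40, 15), (40, 45)]:
            mask |= disc_mask((64, 64), c, 4)
        labels = identify_primary_objects(BinaryMask(mask), 4, 20, kind="nuclei")
        assert labels.n_objects == 5

    def test_undersized_disc_discarded(self):
        mask = disc_mask((32, 32), (16, 16), 1.3)  # ~2 px diameter
        labels = identify_primary_objects(BinaryMask(mask), 4, 20)
        assert labels.n_objects == 0

    def test_touching_nuclei_are_declumped(self):
        mask = disc_mask((40, 40), (20, 16), 5) | disc_mask((40, 40), (20, 25), 5)
        labels = identify_primary_objects(BinaryMask(mask), 4, 20, kind="nuclei")
        assert labels.n_objects == 2

    def test_empty_foreground_gives_empty_map(self):
        labels = identify_primary_objects(BinaryMask(np.zeros((16, 16), bool)), 4, 20)
        assert labels.n_objects == 0

    def test_enclosed_holes_are_filled(self):
        mask = disc_mask((64, 64), (32, 32), 20) & ~disc_mask((64, 64), (30, 30), 3)
        labels = identify_primary_objects(BinaryMask(mask), 10, 60, kind="lumen")
        assert labels.n_objects == 1
        assert labels.data[30, 30] == 1

    def test_invalid_diameter_range_rejected(self):
        with pytest.raises(ValueError):
            identify_primary_objects(BinaryMask(np.zeros((8, 8), bool)), 20, 4)

    def test_phantom_lumina_recovered_exactly(self, small_phantom):
        spec, stack, truth, _ = small_phantom
        gray_mask = BinaryMask(stack.gray() < 0.12)  # inverted tissue
        labels = identify_primary_objects(gray_mask, 25, 800, kind="lumen")
        assert labels.n_objects == spec.n_follicles


class TestMeasureShape:
    def test_large_disc_form_factor_is_one(self):
        mask = disc_mask((256, 256), (128, 128), 64)
        labels = identify_primary_objects(BinaryMask(mask), 16, 200)
        (rec,) = measure_shape(labels, pixel_size=1.0)
        assert rec.form_factor == pytest.approx(1.0, abs=0.05)
        assert rec.area_px == mask.sum()

    def test_square_form_factor_matches_closed_form(self):
        assert 4 * np.pi * 1 / 4**2 == pytest.approx(np.pi / 4)  # analytic s=1
        mask = np.zeros((40, 40), bool)
        mask[10:30, 10:30] = True
        labels = LabelMap(mask.astype(int))
        (rec,) = measure_shape(labels, 1.0)
        assert rec.form_factor == pytest.approx(np.pi / 4, abs=0.05)

    def test_thin_bar_form_factor_matches_closed_form(self):
        analytic = 4 * np.pi * 10 / 22**2  # 1x10 rectangle, P = 22
        assert analytic == pytest.approx(0.260, abs=0.001)
        mask = np.zeros((20, 20), bool)
        mask[9, 5:15] = True
        (rec,) = measure_shape(LabelMap(mask.astype(int)), 1.0)
        assert rec.form_factor == pytest.approx(analytic, abs=0.05)

    @pytest.mark.parametrize("radius", [16, 24, 40])
    def test_disc_form_factor_within_tolerance_down_to_r16(self, radius):
        mask = disc_mask((128, 128), (64, 64), radius)
        (rec,) = measure_shape(LabelMap(mask.astype(int)), 1.0)
        assert abs(rec.form_factor - 1.0) <= 0.05

    def test_perimeter_agrees_with_convex_polygon_oracle(self):
        # convex blob: ellipse; oracle = perimeter of the convex hull polygon
        yy, xx = np.mgrid[:120, :120]
        mask = ((yy - 60) / 40.0) ** 2 + ((xx - 60) / 25.0) ** 2 < 1
        from scipy.spatial import ConvexHull
        pts = np.argwhere(mask)
        hull = ConvexHull(pts)
        poly = pts[hull.vertices]
        oracle = np.sqrt(((np.roll(poly, -1, 0) - poly) ** 2).sum(1)).sum()
        (rec,) = measure_shape(LabelMap(mask.astype(int)), 1.0)
        assert rec.perimeter_px == pytest.approx(oracle, rel=0.05)

    def test_area_scales_with_pixel_size(self):
        mask = disc_mask((64, 64), (32, 32), 10)
        (rec,) = measure_shape(LabelMap(mask.astype(int)), 0.5)
        assert rec.area_um2 == rec.area_px * 0.25


class TestFilterByFormFactor:
    def _disc_and_bar(self):
        canvas = np.zeros((80, 80), int)
        canvas[disc_mask((80, 80), (25, 25), 15)] = 1
        canvas[60, 10:70] = 2  # thin bar
        labels = LabelMap(canvas)
        return labels, measure_shape(labels, 1.0)

    def test_default_threshold_keeps_disc_drops_bar(self):
        labels, shapes = self._disc_and_bar()
        kept = filter_by_form_factor(labels, shapes, 0.3)
        assert kept.n_objects == 1
        assert kept.data[25, 25] == 1 and kept.data[60, 40] == 0

    def test_boundary_is_inclusive(self):
        labels = LabelMap(disc_mask((40, 40), (20, 20), 10).astype(int))
        shapes = [ShapeRecord(label=1, area_px=1, area_um2=1, perimeter_px=1,
                              form_factor=0.3)]
        assert filter_by_form_factor(labels, shapes, 0.3).n_objects == 1

    def test_survivors_relabelled_in_order(self):
        labels, shapes = self._disc_and_bar()
        # permissive threshold keeps both objects with ids preserved
        kept = filter_by_form_factor(labels, shapes, 0.04)
        assert kept.n_objects == 2
        kept_disc_only = filter_by_form_factor(labels, shapes, 0.3)
        assert set(np.unique(kept_disc_only.data)) == {0, 1}

    def test_count_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(5)
        blobs = rng.random((128, 128)) > 0.72
        blobs = ndi.binary_closing(blobs, np.ones((3, 3)))
        labels = identify_primary_objects(BinaryMask(blobs), 2, 100, declump=False)
        shapes = measure_shape(labels, 1.0)
        counts = [
            filter_by_form_factor(labels, shapes, t).n_objects
            for t in np.arange(0.1, 1.0, 0.1)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_threshold_domain_enforced(self, bad):
        labels, shapes = self._disc_and_bar()
        with pytest.raises(ValueError):
            filter_by_form_factor(labels, shapes, bad)


class TestPropagateFollicles:
    def test_barrier_ring_stops_growth(self):
        yy, xx = np.mgrid[:101, :101]
        dd = (yy - 50) ** 2 + (xx - 50) ** 2
        lumen = LabelMap((dd <= 10**2).astype(int), "lumen")
        barrier = (dd >= 25**2) & (dd < 27**2)
        fol = propagate_follicles(lumen, BinaryMask(~barrier), 30)
        radius = np.sqrt(dd[fol.data == 1])
        assert radius.max() <= 25.0
        assert radius.max() >= 23.0  # reaches the barrier, not stopped early
        assert (fol.data[lumen.data > 0] == 1).all()

    def test_expansion_cap_without_barrier(self):
        yy, xx = np.mgrid[:121, :121]
        dd = (yy - 60) ** 2 + (xx - 60) ** 2
        lumen = LabelMap((dd <= 10**2).astype(int), "lumen")
        fol = propagate_follicles(lumen, BinaryMask(np.ones((121, 121), bool)), 30)
        sel = fol.data == 1
        d = np.sqrt(dd)
        assert d[sel].max() == pytest.approx(40.0, abs=1.0)
        assert sel[d <= 36].all()  # chamfer metric shrinks odd angles <= ~8%

    def test_tied_pixel_goes_to_lower_label(self):
        seeds = np.zeros((21, 41), int)
        seeds[10, 5] = 1
        seeds[10, 35] = 2
        fol = propagate_follicles(LabelMap(seeds, "lumen"),
                                  BinaryMask(np.ones((21, 41), bool)), 40)
        assert fol.data[10, 20] == 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            propagate_follicles(LabelMap(np.zeros((8, 8), int)),
                                BinaryMask(np.ones((9, 8), bool)), 30)

    def test_zero_expansion_keeps_only_lumina(self):
        seeds = disc_mask((40, 40), (20, 20), 8).astype(int)
        fol = propagate_follicles(LabelMap(seeds, "lumen"),
                                  BinaryMask(np.ones((40, 40), bool)), 0)
        assert np.array_equal(fol.data > 0, seeds > 0)


class TestDeriveEpithelium:
    def test_annulus_area_recovered(self):
        fol = LabelMap(disc_mask((64, 64), (32, 32), 20).astype(int), "follicle")
        lum = LabelMap(disc_mask((64, 64), (32, 32), 10).astype(int), "lumen")
        epi = derive_epithelium(fol, lum)
        expected = np.pi * (400 - 100)
        assert (epi.data == 1).sum() == pytest.approx(expected, rel=0.05)
        assert not (epi.data.astype(bool) & lum.data.astype(bool)).any()

    def test_follicle_equal_to_lumen_is_flagged_empty(self):
        disc = disc_mask((32, 32), (16, 16), 8).astype(int)
        epi = derive_epithelium(LabelMap(disc, "follicle"), LabelMap(disc, "lumen"))
        assert epi.n_objects == 0
        assert epi.meta["empty_labels"] == [1]

    def test_orphan_lumen_raises_naming_label(self):
        lum = LabelMap(disc_mask((32, 32), (16, 16), 5).astype(int), "lumen")
        fol = LabelMap(np.zeros((32, 32), int), "follicle")
        with pytest.raises(ValueError, match="1"):
            derive_epithelium(fol, lum)

    def test_phantom_epithelium_areas_within_5pct(self, mid_phantom):
        from follimetry import PipelineConfig, run_morphometry
        spec, stack, truth, _ = mid_phantom
        res = run_morphometry(stack, PipelineConfig())
        got = np.sort(res.records_frame["epithelium_area_um2"].to_numpy())
        want = np.sort(truth.follicles["epithelium_area_um2"].to_numpy())
        assert got == pytest.approx(want, rel=0.05)


class TestRelations:
    def test_child_assigned_by_centroid(self):
        parents = LabelMap(disc_mask((64, 64), (32, 32), 20).astype(int) * 3)
        child_in = LabelMap(disc_mask((64, 64), (32, 32), 3).astype(int))
        child_out = LabelMap(disc_mask((64, 64), (5, 58), 3).astype(int))
        assert relate_objects(child_in, parents)["parent"].tolist() == [3]
        assert relate_objects(child_out, parents)["parent"].tolist() == [0]

    def test_intraluminal_masking_keeps_only_lumen_nuclei(self):
        lumina = LabelMap(disc_mask((64, 64), (20, 20), 10).astype(int) * 5)
        nuclei = np.zeros((64, 64), int)
        nuclei[disc_mask((64, 64), (20, 20), 3)] = 1   # inside lumen 5
        nuclei[disc_mask((64, 64), (50, 50), 3)] = 2   # outside
        table = mask_intraluminal_nuclei(LabelMap(nuclei, "nuclei"), lumina)
        assert table["child"].tolist() == [1]
        assert table["parent"].tolist() == [5]

    def test_phantom_nucleus_counts_match_truth(self, small_phantom):
        from follimetry import PipelineConfig, run_morphometry
        spec, stack, truth, _ = small_phantom
        res = run_morphometry(stack, PipelineConfig())
        assert res.nuclei.n_objects == (
            truth.follicles["n_epithelial_nuclei"].sum()
            + truth.follicles["n_intraluminal_nuclei"].sum()
        )
        assert len(res.dead_relations) == truth.follicles["n_intraluminal_nuclei"].sum()


class TestLabelOverrides:
    def test_drop_and_add(self):
        canvas = np.zeros((40, 40), int)
        canvas[disc_mask((40, 40), (10, 10), 4)] = 1
        canvas[disc_mask((40, 40), (30, 30), 4)] = 2
        labels = LabelMap(canvas, "lumen")
        out = apply_label_overrides(labels, drop=(1,),
                                    add_mask=disc_mask((40, 40), (10, 30), 4))
        assert out.n_objects == 2
        assert out.data[30, 30] == 1  # survivor relabeled first
        assert out.data[10, 30] == 2  # added object appended
        assert out.data[10, 10] == 0
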