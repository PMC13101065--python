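"""Cell-mask extraction, background correction, auto-vs-manual agreement."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from qpmorph import (
    BoundingBox,
    CellMask,
    HeightMap,
    background_correct,
    compare_masks,
    crop_cells,
    keep_largest,
    local_threshold_median,
    morphological_cleanup,
    percent_error,
    segment_cell,
)
from qpmorph.segmentation import aggregate_reports


def disk_mask(n=201, radius=15, center=None):
    c = center or (n // 2, n // 2)
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= radius**2


class TestCrop:
    def make_map(self):
        return HeightMap(height_um=np.arange(64 * 64, dtype=float).reshape(64, 64))

    def test_top_left_quadrant(self):
        hm = self.make_map()
        (cid, crop), = crop_cells(hm, [BoundingBox("1", "a", 0, 0, 32, 32)])
        assert cid == "a"
        assert np.array_equal(crop.height_um, hm.height_um[:32, :32])

    def test_clipping_warns(self):
        hm = self.make_map()
        with pytest.warns(UserWarning, match="clipped"):
            (_, crop), = crop_cells(hm, [BoundingBox("1", "b", 37, 0, 32, 32)])
        assert crop.height_um.shape == (32, 27)

    def test_fully_outside_raises_with_cell_id(self):
        hm = self.make_map()
        with pytest.raises(ValueError, match="ghost"):
            crop_cells(hm, [BoundingBox("1", "ghost", 100, 100, 16, 16)])

    def test_order_preserved(self):
        hm = self.make_map()
        boxes = [BoundingBox("1", n, 8 * i, 0, 8, 8) for i, n in enumerate("xyz")]
        out = crop_cells(hm, boxes)
        assert [cid for cid, _ in out] == ["x", "y", "z"]


class TestLocalThreshold:
    def test_constant_image_all_background(self):
        assert not local_threshold_median(np.full((120, 120), 7.0)).any()

    def test_disk_recovered(self):
        truth = disk_mask()
        mask = local_threshold_median(10.0 * truth)
        iou = np.count_nonzero(mask & truth) / np.count_nonzero(mask | truth)
        assert iou >= 0.95

    def test_disk_on_ramp_recovered(self):
        """The local median adapts to a linear background gradient."""
        truth = disk_mask()
        ramp = np.linspace(0, 2, 201)[None, :].repeat(201, 0)
        mask = local_threshold_median(10.0 * truth + ramp)
        iou = np.count_nonzero(mask & truth) / np.count_nonzero(mask | truth)
        assert iou >= 0.90

    @pytest.mark.parametrize("shift", [-31.5, 0.0, 1e4])
    def test_shift_invariance(self, shift):
        img = 5.0 * disk_mask(101, 10) + np.linspace(0, 1, 101)[None, :]
        assert np.array_equal(
            local_threshold_median(img), local_threshold_median(img + shift)
        )

    def test_quantized_matches_exact_on_small_image(self):
        rng = np.random.default_rng(0)
        img = np.round(rng.normal(0, 1, (40, 40)), 1)  # coarse values: no sub-step diffs
        a = local_threshold_median(img, radius_px=5, method="quantized")
        b = local_threshold_median(img, radius_px=5, method="exact")
        assert (a == b).mean() > 0.98  # boundary columns may differ in tie handling

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            local_threshold_median(np.ones((20, 20)), radius_px=0)


class TestCleanup:
    def test_isolated_pixels_removed(self):
        rng = np.random.default_rng(1)
        mask = np.zeros((50, 50), bool)
        idx = rng.choice(2500, 30, replace=False)
        mask.ravel()[idx] = True
        mask &= ~ndimage.binary_dilation(mask) ^ mask  # keep only isolated ones
        assert not morphological_cleanup(mask).any()

    def test_large_square_idempotent(self):
        sq = np.zeros((40, 40), bool)
        sq[10:30, 10:30] = True
        assert np.array_equal(morphological_cleanup(sq), sq)

    def test_empty_identity(self):
        assert not morphological_cleanup(np.zeros((20, 20), bool)).any()

    def test_never_exceeds_dilation(self):
        rng = np.random.default_rng(2)
        mask = rng.random((60, 60)) > 0.6
        out = morphological_cleanup(mask)
        dilated = ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool))
        assert not (out & ~dilated).any()


class TestKeepLargest:
    def test_largest_kept(self):
        mask = np.zeros((60, 60), bool)
        mask[5:30, 5:25] = True    # 500 px
        mask[40:50, 40:60] = True  # 200 px
        out = keep_largest(mask)
        assert out.n_components_before_selection == 2
        assert np.count_nonzero(out.mask) == 500
        assert out.mask[10, 10] and not out.mask[45, 45]

    def test_single_blob_unchanged(self):
        blob = disk_mask(41, 10)
        out = keep_largest(blob)
        assert np.array_equal(out.mask, blob)

    def test_tie_breaks_row_major(self):
        mask = np.zeros((30, 30), bool)
        mask[20:25, 0:20] = True  # second in row-major order, 100 px
        mask[0:5, 5:25] = True    # first in row-major order, 100 px
        out = keep_largest(mask)
        assert out.mask[0, 5] and not out.mask[20, 0]

    def test_empty_is_warned_not_raised(self):
        with pytest.warns(UserWarning):
            out = keep_largest(np.zeros((10, 10), bool))
        assert out.empty and not out.mask.any()

    def test_output_area_is_max_component_area(self):
        rng = np.random.default_rng(3)
        mask = ndimage.binary_opening(rng.random((80, 80)) > 0.4)
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), int))
        if n:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            assert np.count_nonzero(keep_largest(mask).mask) == int(sizes.max())


class TestBackgroundCorrection:
    def test_uniform_offset_removed(self):
        cell = np.zeros((50, 50))
        cell[20:30, 20:30] = 2.0
        mask = cell > 0
        out = background_correct(cell + 5.0, mask)
        assert out[~mask].mean() == pytest.approx(0.0, abs=1e-12)
        # within-mask values shifted by the same -5
        assert np.allclose(out[mask], cell[mask])

    def test_zero_mean_noise_small_shift(self):
        rng = np.random.default_rng(4)
        img = rng.normal(0, 0.1, (100, 100))
        mask = np.zeros((100, 100), bool)
        mask[40:60, 40:60] = True
        out = background_correct(img, mask)
        sem = 0.1 / np.sqrt((~mask).sum())
        assert abs((out - img).mean()) <= 3 * sem

    def test_all_background_zero_mean(self):
        img = np.random.default_rng(5).normal(3, 1, (30, 30))
        out = background_correct(img, np.zeros((30, 30), bool))
        assert out.mean() == pytest.approx(0.0, abs=1e-10)

    def test_idempotent(self):
        img = np.random.default_rng(6).normal(2, 1, (40, 40))
        mask = disk_mask(40, 8, (20, 20))
        once = background_correct(img, mask)
        twice = background_correct(once, mask)
        assert np.allclose(once, twice, atol=1e-12)

    def test_full_mask_raises(self):
        with pytest.raises(ValueError, match="no background"):
            background_correct(np.ones((10, 10)), np.ones((10, 10), bool))


class TestPercentError:
    @pytest.mark.parametrize("auto,manual,expected", [(3.0, 3.0, 0.0), (1.1, 1.0, 10.0)])
    def test_closed_form(self, auto, manual, expected):
        assert percent_error(auto, manual) == pytest.approx(expected, abs=1e-9)

    def test_zero_manual_flagged_nan(self):
        assert np.isnan(percent_error(1.0, 0.0))


class TestCompareMasks:
    def test_identical(self):
        m = CellMask(disk_mask(41, 10))
        feats = {"projected_area": 314.0, "perimeter": 63.0}
        rep = compare_masks(m, m, feats, feats)
        assert rep.iou == 1.0
        assert all(v == 0.0 for v in rep.percent_errors.values())

    def test_disjoint_iou_zero(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[:5], b[10:] = True, True
        assert compare_masks(CellMask(a), CellMask(b)).iou == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            compare_masks(CellMask(np.ones((4, 4), bool)), CellMask(np.ones((5, 5), bool)))

    def test_errors_match_independent_recomputation(self):
        from qpmorph import CalibrationParams, extract_all

        calib = CalibrationParams(pixel_size_um=1.0)
        auto = disk_mask(61, 20, (30, 30))
        manual = ndimage.binary_erosion(auto, np.ones((3, 3), bool))
        h = np.where(auto, 1.5, 0.0)
        fa = extract_all(h, auto, calib).to_dict()
        fm = extract_all(h, manual, calib).to_dict()
        rep = compare_masks(CellMask(auto), CellMask(manual), fa, fm)
        for name in ("volume", "projected_area", "perimeter"):
            assert rep.percent_errors[name] == pytest.approx(
                abs(fa[name] - fm[name]) / abs(fm[name]) * 100.0
            )

    def test_aggregate_is_mean_of_cells(self):
        reps = [
            compare_masks(CellMask(disk_mask(21, 5)), CellMask(disk_mask(21, 5)),
                          {"a": x}, {"a": 1.0})
            for x in (1.1, 1.3)
        ]
        agg = aggregate_reports(reps)
        assert agg["a"] == pytest.approx(np.mean([10.0, 30.0]))


def test_pipeline_determinism():
    """Same crop, same config: bit-identical mask."""
    rng = np.random.default_rng(7)
    img = 3.0 * disk_mask(121, 25) + rng.normal(0, 0.1, (121, 121))
    m1, p1 = segment_cell(img)
    m2, p2 = segment_cell(img)
    assert np.array_equal(m1.mask, m2.mask) and np.array_equal(p1, p2)
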