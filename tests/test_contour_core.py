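"""Geometry primitives: sampling, normalization, ordering, masks, metrics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contourlw import contour_core as cc


def tour_length(pts):
    return float(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum())


class TestSampling:
    def test_equal_arc_length_spacing(self, unit_square):
        pts = cc.sample_contour_points(unit_square, 8)
        gaps = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        assert np.allclose(gaps, 0.5, atol=1e-9)

    def test_square_corners_recovered(self, unit_square):
        pts = cc.sample_contour_points(unit_square, 4)
        assert np.allclose(pts, unit_square)

    def test_nested_uniform_sampling(self, rng):
        poly = rng.random((7, 2)) * 10
        n = 12
        coarse = cc.sample_contour_points(poly, n)
        fine = cc.sample_contour_points(poly, 4 * n)
        assert np.allclose(coarse, fine[::4], atol=1e-9)

    def test_phase_offsets_start_point(self, unit_square):
        pts = cc.sample_contour_points(unit_square, 4, phase=0.125)
        assert np.allclose(pts[0], [0.5, 0.0])

    def test_degenerate_contour_rejected(self):
        flat = np.zeros((4, 2))
        with pytest.raises(ValueError, match="degenerate"):
            cc.sample_contour_points(flat, 8)


class TestBoxNormalize:
    def test_rectangle_maps_to_unit_corners(self):
        rect = np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 4.0], [0.0, 4.0]])
        out = cc.box_normalize(rect)
        assert np.allclose(out, [[0, 0], [1, 0], [1, 1], [0, 1]])

    def test_identity_on_full_span_unit_points(self, unit_square):
        assert np.allclose(cc.box_normalize(unit_square), unit_square)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_output_spans_unit_box(self, seed):
        pts = np.random.default_rng(seed).random((128, 2)) * 50 + 3
        out = cc.box_normalize(pts)
        assert np.allclose(out.min(axis=0), 0.0)
        assert np.allclose(out.max(axis=0), 1.0)

    def test_zero_extent_rejected(self):
        with pytest.raises(ValueError, match="degenerate box"):
            cc.box_normalize(np.array([[1.0, 0.0], [1.0, 2.0], [1.0, 5.0]]))


class TestTspOrdering:
    def test_square_perimeter(self, unit_square, rng):
        shuffled = unit_square[rng.permutation(4)]
        ordered = cc.order_points_tsp(shuffled)
        assert tour_length(ordered) == pytest.approx(4.0)

    def brute_force_length(self, pts):
        n = len(pts)
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        best = np.inf
        for perm in itertools.permutations(range(1, n)):
            tour = (0,) + perm
            best = min(best, sum(d[tour[i], tour[(i + 1) % n]] for i in range(n)))
        return best

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_optimum_on_convex_points(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 9))
        ang = np.sort(r.uniform(0, 2 * np.pi, n))
        pts = np.stack([np.cos(ang), 0.6 * np.sin(ang)], axis=1) * r.uniform(0.5, 2.0)
        ordered = cc.order_points_tsp(pts[r.permutation(n)])
        assert tour_length(ordered) == pytest.approx(self.brute_force_length(pts))

    def test_never_worse_than_input_order(self, rng):
        pts = rng.random((15, 2))
        ordered = cc.order_points_tsp(pts)
        assert tour_length(ordered) <= tour_length(pts) + 1e-12

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            cc.order_points_tsp(np.zeros((2, 2)))


class TestRasterize:
    def test_square_area(self):
        poly = np.array([[10.0, 10.0], [60.0, 10.0], [60.0, 60.0], [10.0, 60.0]])
        mask = cc.rasterize_contour(poly, 256, 256)
        assert abs(mask.sum() - 2500) <= 25  # within 1%

    def test_contour_outside_image_is_empty(self):
        poly = np.array([[300.0, 300.0], [350.0, 300.0], [325.0, 350.0]])
        assert cc.rasterize_contour(poly, 256, 256).sum() == 0

    def test_ellipse_area_analytic(self):
        theta = np.linspace(0, 2 * np.pi, 257)[:-1]
        ell = np.stack([128 + 40 * np.cos(theta), 128 + 20 * np.sin(theta)], axis=1)
        mask = cc.rasterize_contour(ell, 256, 256)
        assert abs(mask.sum() - np.pi * 40 * 20) / (np.pi * 40 * 20) < 0.02

    def test_reextracted_boundary_preserves_area(self):
        theta = np.linspace(0, 2 * np.pi, 257)[:-1]
        ell = np.stack([128 + 40 * np.cos(theta), 128 + 20 * np.sin(theta)], axis=1)
        mask = cc.rasterize_contour(ell, 256, 256)
        boundary = cc.extract_boundary(mask)
        mask2 = cc.rasterize_contour(boundary, 256, 256)
        # idempotent within one pixel-row of boundary
        assert abs(int(mask2.sum()) - int(mask.sum())) <= len(boundary)


class TestMaskAp:
    def test_perfect_predictions_score_one(self):
        a = cc.rasterize_contour(np.array([[5, 5], [40, 5], [40, 40], [5, 40]]), 64, 64)
        b = cc.rasterize_contour(np.array([[45, 45], [60, 45], [60, 60], [45, 60]]), 64, 64)
        rep = cc.mask_ap([(a, 0.7), (b, 0.9)], [a, b])
        assert rep.ap == rep.ap50 == rep.ap75 == 1.0

    def test_disjoint_prediction_scores_zero(self):
        a = np.zeros((32, 32), np.uint8)
        a[:8, :8] = 1
        b = np.zeros((32, 32), np.uint8)
        b[20:, 20:] = 1
        rep = cc.mask_ap([(a, 0.9)], [b])
        assert rep.ap == 0.0

    def test_iou_threshold_boundary(self):
        # IoU exactly 0.6: counts at the 0.5 threshold, not at 0.75
        truth = np.zeros((20, 20), np.uint8)
        truth[0:10, 0:10] = 1  # area 100
        pred = np.zeros((20, 20), np.uint8)
        pred[0:10, 0:15] = 1  # overlap 100, union 150 -> IoU 2/3 ~ 0.667
        assert cc.mask_iou(pred, truth) == pytest.approx(2 / 3)
        rep = cc.mask_ap([(pred, 0.9)], [truth])
        assert rep.ap50 == 1.0
        assert rep.ap75 == 0.0

    def test_both_empty_reported_as_skipped(self):
        rep = cc.mask_ap([[]], [[]])
        assert rep.ap is None
        assert rep.skipped_images == [0]


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        rep = cc.regression_metrics([50.0, 100.0], [50.0, 100.0])
        assert (rep.mae, rep.mse, rep.mape, rep.r2) == (0.0, 0.0, 0.0, 1.0)

    def test_hand_computed_two_point_case(self):
        rep = cc.regression_metrics([60.0, 90.0], [50.0, 100.0])
        assert rep.mae == pytest.approx(10.0)
        assert rep.mse == pytest.approx(100.0)
        assert rep.mape == pytest.approx(15.0)
        assert rep.r2 == pytest.approx(0.84)

    def test_invariants_hold_on_random_data(self, rng):
        y = rng.uniform(30, 120, 50)
        yhat = y + rng.normal(0, 5, 50)
        rep = cc.regression_metrics(yhat, y)
        assert rep.mae**2 <= rep.mse + 1e-12
        assert rep.r2 <= 1.0

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError, match="MAPE"):
            cc.regression_metrics([1.0], [0.0])

    def test_constant_truth_gives_nan_r2(self):
        rep = cc.regression_metrics([1.0, 2.0], [5.0, 5.0])
        assert np.isnan(rep.r2)


class TestCocoIo:
    def test_polygon_round_trip(self, tmp_path, rng):
        poly = rng.random((16, 2)) * 90
        path = tmp_path / "inst.json"
        cc.write_coco(
            path,
            [{"id": 1, "width": 96, "height": 96, "file_name": "a.png"}],
            [{"id": 10, "image_id": 1, "segmentation": poly.flatten().tolist()}],
        )
        images, anns = cc.read_coco(path)
        assert images[0]["file_name"] == "a.png"
        assert np.allclose(anns[0]["segmentation"], np.round(poly, 3))
        assert anns[0]["category_id"] == 1

    def test_rle_round_trip(self, rng):
        mask = (rng.random((17, 13)) > 0.6).astype(np.uint8)
        back = cc.rle_to_mask(cc.mask_to_rle(mask))
        assert np.array_equal(mask, back)
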