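"""Contour extractor: feature shapes, aggregation, CSA, losses, training."""

import numpy as np
import pytest

from contourlw import cien, synthetic_fixtures as sf
from contourlw.autodiff import Tensor
from contourlw.nn_blocks import MhsaBlock


@pytest.fixture(scope="module")
def desk_model():
    return cien.CienModel(cien.CienConfig.desk(), seed=0)


@pytest.fixture(scope="module")
def desk_features(desk_model):
    img = np.random.default_rng(0).integers(0, 255, (96, 96, 3)).astype(np.uint8)
    return desk_model.features(img)


class TestFeatureExtraction:
    def test_backbone_stride_pyramid(self, desk_model):
        x = Tensor(np.zeros((1, 3, 96, 96)))
        sizes = [o.shape[2] for o in desk_model.backbone(x)]
        assert sizes == [24, 12, 6, 3]  # strides 4, 8, 16, 32

    def test_deterministic_given_weights(self, desk_model):
        img = np.random.default_rng(1).integers(0, 255, (96, 96, 3)).astype(np.uint8)
        h1, _, _ = desk_model.features(img)
        h2, _, _ = desk_model.features(img)
        assert np.array_equal(h1.data, h2.data)

    def test_head_output_shapes(self, desk_features):
        heatmap, reg, fprime = desk_features
        assert heatmap.shape == (1, 1, 24, 24)
        assert reg.shape == (1, 64 * 2, 24, 24)
        assert fprime.shape == (1, 30, 24, 24)

    def test_heatmap_strictly_in_unit_interval(self, desk_features):
        hm = desk_features[0].data
        assert hm.min() > 0.0 and hm.max() < 1.0

    def test_full_scale_stride_arithmetic(self):
        model = cien.CienModel(cien.CienConfig(), seed=0)
        maps = model.backbone(Tensor(np.zeros((1, 3, 576, 768))))
        assert [m.shape[2:] for m in maps] == [
            (144, 192), (72, 96), (36, 48), (18, 24)
        ]

    def test_ida_single_element_series_returns_projection(self, desk_model):
        o1 = Tensor(np.random.default_rng(2).random((1, 12, 24, 24)))
        out = desk_model.ida_aggregate([o1])
        w, b = desk_model.convs["proj0"]
        expected = np.einsum("bchw,oc->bohw", o1.data, w.data[:, :, 0, 0]) + b.data[None, :, None, None]
        assert np.allclose(out.data, expected)


class TestContourStages:
    def test_zero_regression_collapses_to_center(self, desk_model):
        reg = Tensor(np.zeros((1, 128, 24, 24)))
        contour = desk_model.initialize_contour(reg, (7.0, 9.0))
        assert np.allclose(contour.data, [7.0, 9.0])

    def test_handcrafted_offsets_are_added_exactly(self, desk_model):
        offsets = np.random.default_rng(3).normal(0, 2, (64, 2))
        reg = Tensor(np.tile(offsets.reshape(1, 128, 1, 1), (1, 1, 24, 24)))
        contour = desk_model.initialize_contour(reg, (5.0, 6.0))
        assert np.allclose(contour.data, offsets + [5.0, 6.0])

    def test_vertex_count_conserved_through_refinement(self, desk_model, desk_features):
        _, reg, fprime = desk_features
        stages = desk_model.contours_from_centers(reg, fprime, [(12.0, 12.0), (5.0, 18.0)])
        assert len(stages) == 2
        for per_center in stages:
            assert len(per_center) == 3  # init + two CSA evolutions
            assert all(s.shape == (64, 2) for s in per_center)

    def test_zeroed_offset_head_is_identity(self, desk_features):
        # fresh model: offset heads start at zero, so CSA must not move points
        model = cien.CienModel(cien.CienConfig.desk(), seed=4)
        _, reg, fprime = desk_features
        stages = model.contours_from_centers(reg, fprime, [(12.0, 12.0)])[0]
        assert np.allclose(stages[0].data, stages[2].data)

    def test_csa_dim_is_point_feature_plus_embedding(self):
        cfg = cien.CienConfig.desk()
        assert cfg.csa_dim == 30 + 2
        assert cien.CienConfig().csa_dim == 254 + 2


class TestMhsaBlock:
    def test_zero_input_zero_params_gives_zero(self):
        blk = MhsaBlock(32, 8, np.random.default_rng(0))
        for p in blk.parameters():
            p.data[:] = 0.0
        out = blk(Tensor(np.zeros((5, 32))))
        assert np.allclose(out.data, 0.0)

    def test_output_shape_matches_input(self, rng):
        blk = MhsaBlock(32, 8, np.random.default_rng(1))
        out = blk(Tensor(rng.random((7, 32))))
        assert out.shape == (7, 32)

    def test_permutation_equivariance(self, rng):
        blk = MhsaBlock(32, 4, np.random.default_rng(2))
        x = rng.random((9, 32))
        perm = rng.permutation(9)
        assert np.allclose(blk(Tensor(x[perm])).data, blk(Tensor(x)).data[perm])

    def test_attention_rows_are_distributions(self, rng):
        blk = MhsaBlock(32, 8, np.random.default_rng(3))
        blk.attention(Tensor(rng.random((6, 32))))
        assert np.allclose(blk.last_attention.sum(axis=-1), 1.0)


class TestLosses:
    def test_focal_loss_vanishes_for_perfect_prediction(self):
        target = np.zeros((4, 4))
        target[1, 1] = 1.0
        pred = np.full((1, 1, 4, 4), 1e-7)
        pred[0, 0, 1, 1] = 1 - 1e-7
        loss = cien.focal_heatmap_loss(Tensor(pred), target)
        assert float(loss.data) < 1e-4

    def test_focal_loss_hand_computed_case(self):
        target = np.array([[1.0, 0.3], [0.0, 0.0]])
        loss = cien.focal_heatmap_loss(Tensor(np.full((1, 1, 2, 2), 0.5)), target)
        p = 0.5
        hand = -(
            (1 - p) ** 2 * np.log(p)
            + (1 - 0.3) ** 4 * p**2 * np.log(1 - p)
            + 2 * p**2 * np.log(1 - p)
        )
        assert float(loss.data) == pytest.approx(hand, rel=1e-4)

    def test_focal_normalization_by_object_count(self):
        one = np.zeros((6, 6))
        one[1, 1] = 1.0
        two = np.zeros((12, 6))
        two[1, 1] = 1.0
        two[7, 1] = 1.0  # same local structure, duplicated
        one_pred = np.full((1, 1, 6, 6), 0.4)
        two_pred = np.full((1, 1, 12, 6), 0.4)
        l1 = float(cien.focal_heatmap_loss(Tensor(one_pred), one).data)
        l2 = float(cien.focal_heatmap_loss(Tensor(two_pred), two).data)
        assert l2 == pytest.approx(l1, rel=1e-9)

    def test_no_objects_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            loss = cien.focal_heatmap_loss(Tensor(np.full((1, 1, 3, 3), 0.2)), np.zeros((3, 3)))
        assert float(loss.data) == 0.0

    @pytest.mark.parametrize(
        "components,expected",
        [((1.0, 1.0, 1.0, 1.0), 3.0), ((0.0, 0.0, 0.0, 0.0), 0.0), ((0.2, 0.4, 0.6, 0.8), 1.5)],
    )
    def test_total_loss_weighting(self, components, expected):
        assert cien.cien_total_loss(*components) == pytest.approx(expected)


@pytest.fixture(scope="module")
def smoke_run(small_scene_splits):
    scenes = small_scene_splits["train"][:10]
    cfg = cien.CienConfig.desk(epochs=4)
    model, hist = cien.train_cien(scenes, cfg, seed=0, supervision="ot")
    return scenes, cfg, model, hist


class TestTraining:
    def test_loss_history_finite_and_decreasing_in_trend(self, smoke_run):
        hist = smoke_run[3]
        assert np.all(np.isfinite(hist["loss"]))
        assert hist["loss"][-1] < hist["loss"][0]

    def test_fixed_seed_reproduces_first_epoch(self, smoke_run):
        scenes, _, _, hist = smoke_run
        _, h2 = cien.train_cien(
            scenes, cien.CienConfig.desk(epochs=1), seed=0, supervision="ot"
        )
        assert h2["loss"][0] == hist["loss"][0]

    def test_km_supervision_runs_through_same_loop(self, small_scene_splits):
        scenes = small_scene_splits["train"][:4]
        _, hist = cien.train_cien(
            scenes, cien.CienConfig.desk(epochs=1), seed=0, supervision="km"
        )
        assert np.isfinite(hist["loss"][0])

    def test_inference_contract(self, smoke_run):
        scenes, _, model, _ = smoke_run
        dets = model.infer(scenes[0].image)
        for contour, score in dets:
            assert contour.shape == (64, 2)
            assert 0.0 <= score <= 1.0
        blank = np.zeros((96, 96, 3), np.uint8)
        assert model.infer(blank, threshold=0.999) == []

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            cien.train_cien([], cien.CienConfig.desk())
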