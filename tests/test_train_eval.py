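import numpy as np
import pytest

from znet3d.preprocessing import MaskStack, ModalityStack
from znet3d.train_eval import (
    DiceReport,
    TrainConfig,
    bce_loss,
    dice_coefficient,
    evaluate_dataset,
    export_overlay,
    predict_case,
    split_dataset,
    train_model,
)
from znet3d.znet_model import ZnetConfig, build_znet


def brute_force_dice(a, b):
    """Exhaustive voxel-loop oracle for the dice coefficient."""
    inter = 0
    size_a = 0
    size_b = 0
    for va, vb in zip(a.ravel().tolist(), b.ravel().tolist()):
        size_a += bool(va)
        size_b += bool(vb)
        inter += bool(va) and bool(vb)
    if size_a + size_b == 0:
        return 1.0
    return 2.0 * inter / (size_a + size_b)


@pytest.fixture
def tiny_model():
    cfg = ZnetConfig(depth=2, base_width=4, input_size=(16, 16, 16))
    return build_znet(cfg, seed=0)


@pytest.fixture
def tiny_pair(phantom_case):
    from znet3d.preprocessing import stack_case

    return stack_case(phantom_case, (16, 16, 16))


class TestBceLoss:
    def test_uniform_half_equals_ln2(self, rng):
        target = (rng.random((3, 4, 4, 4)) < 0.5).astype(np.float32)
        pred = np.full_like(target, 0.5)
        assert bce_loss(pred, target) == pytest.approx(np.log(2), abs=1e-6)

    def test_limit_to_zero_for_perfect_prediction(self):
        target = np.array([1.0, 0.0])
        for eps in (1e-2, 1e-4, 1e-6):
            pred = np.clip(target, eps, 1 - eps)
            assert bce_loss(pred, target) < -np.log(1 - eps) + 1e-9

    def test_hand_computed_two_voxel_case(self):
        pred = np.array([0.9, 0.2])
        target = np.array([1.0, 0.0])
        expected = np.mean([-np.log(0.9), -np.log(0.8)])
        assert bce_loss(pred, target) == pytest.approx(expected, rel=1e-12)

    def test_nonnegative(self, rng):
        pred = rng.uniform(0.01, 0.99, size=(2, 3, 3, 3))
        target = (rng.random(pred.shape) < 0.5).astype(float)
        assert bce_loss(pred, target) >= 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros((2, 2)), np.zeros((3, 2)))


class TestDiceCoefficient:
    def test_identical_nonempty(self, rng):
        m = (rng.random((6, 6, 6)) < 0.4).astype(np.uint8)
        m[0, 0, 0] = 1
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros_like(a)
        a[0, 0, 0] = 1
        b[1, 1, 1] = 1
        assert dice_coefficient(a, b) == 0.0

    def test_empty_empty_is_one(self):
        z = np.zeros((3, 3, 3), dtype=np.uint8)
        assert dice_coefficient(z, z) == 1.0

    def test_closed_form_half(self):
        a = np.zeros((2, 2, 2), dtype=np.uint8)
        b = np.zeros_like(a)
        a.ravel()[:4] = 1
        b.ravel()[2:6] = 1
        assert dice_coefficient(a, b) == 0.5

    def test_symmetry_and_oracle(self, rng):
        for _ in range(50):
            a = (rng.random((6, 6, 6)) < rng.random()).astype(np.uint8)
            b = (rng.random((6, 6, 6)) < rng.random()).astype(np.uint8)
            d = dice_coefficient(a, b)
            assert d == dice_coefficient(b, a)
            assert d == pytest.approx(brute_force_dice(a, b), abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestTrainConfig:
    def test_defaults_match_protocol(self):
        cfg = TrainConfig()
        assert cfg.epochs == 50
        assert cfg.batch_size == 1

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"epochs": 0},
            {"train_fraction": 1.5},
            {"threshold": -0.1},
            {"learning_rate": -1.0},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)


class TestPredictCase:
    def test_threshold_zero_gives_all_ones(self, tiny_model, tiny_pair):
        pred = predict_case(tiny_model, tiny_pair[0], threshold=0.0)
        assert np.all(pred.data == 1)

    def test_threshold_above_one_gives_all_zeros(self, tiny_model, tiny_pair):
        pred = predict_case(tiny_model, tiny_pair[0], threshold=1.0 + 1e-9)
        assert np.all(pred.data == 0)

    def test_output_shape(self, tiny_model, tiny_pair):
        pred = predict_case(tiny_model, tiny_pair[0], threshold=0.5)
        assert pred.data.shape == (3, 16, 16, 16)


class TestTrainModel:
    def test_loss_history_length_and_finite(self, tiny_model, tiny_pair):
        config = TrainConfig(epochs=3, learning_rate=1e-3, seed=0)
        _, history = train_model(tiny_model, [tiny_pair], config)
        assert len(history.train_loss) == 3
        assert all(np.isfinite(v) for v in history.train_loss)

    def test_determinism(self, tiny_pair):
        cfg = ZnetConfig(depth=2, base_width=4, input_size=(16, 16, 16))
        traces = []
        for _ in range(2):
            model = build_znet(cfg, seed=0)
            _, history = train_model(
                model, [tiny_pair], TrainConfig(epochs=2, learning_rate=1e-3, seed=0)
            )
            traces.append(history.train_loss)
        assert traces[0] == traces[1]

    def test_zero_learning_rate_freezes_weights(self, tiny_pair):
        cfg = ZnetConfig(depth=2, base_width=4, input_size=(16, 16, 16))
        model = build_znet(cfg, seed=0)
        before = [p.data.copy() for p in model.parameters()]
        train_model(model, [tiny_pair], TrainConfig(epochs=2, learning_rate=0.0, seed=0))
        for p, b in zip(model.parameters(), before):
            np.testing.assert_array_equal(p.data, b)

    def test_loss_decreases_over_epoch_windows(self, tiny_pair):
        # mean loss over epochs 10-19 below mean over epochs 0-9
        cfg = ZnetConfig(depth=2, base_width=4, input_size=(16, 16, 16))
        model = build_znet(cfg, seed=0)
        _, history = train_model(
            model, [tiny_pair], TrainConfig(epochs=20, learning_rate=1e-3, seed=0)
        )
        first = np.mean(history.train_loss[:10])
        second = np.mean(history.train_loss[10:])
        assert second < first

    def test_empty_dataset_raises(self, tiny_model):
        with pytest.raises(ValueError):
            train_model(tiny_model, [], TrainConfig(epochs=1))

    def test_channel_mismatch_raises(self, tiny_model, tiny_pair):
        stack, masks = tiny_pair
        bad = MaskStack(data=masks.data[:2], case_id="x")
        with pytest.raises(ValueError, match="channels"):
            train_model(tiny_model, [(stack, bad)], TrainConfig(epochs=1))


class TestEvaluateDataset:
    def test_perfect_predictions_score_one(self, tiny_pair, monkeypatch):
        import znet3d.train_eval as te

        stack, masks = tiny_pair
        monkeypatch.setattr(
            te, "predict_case", lambda model, s, threshold=0.5: masks
        )
        report = te.evaluate_dataset(None, [(stack, masks)], TrainConfig())
        assert report.overall_mean == 1.0

    def test_overall_mean_is_mean_of_region_means(self):
        # aggregation convention: (90.6 + 84.5 + 85.9) / 3 = 87.0
        per_case = [{"WT": 0.906, "TC": 0.845, "ET": 0.859, "case_id": "c"}]
        report = DiceReport.from_per_case(per_case)
        assert report.overall_mean == pytest.approx(0.87, abs=5e-4)

    def test_single_case_means_equal_case(self, tiny_model, tiny_pair):
        report = evaluate_dataset(tiny_model, [tiny_pair], TrainConfig())
        case = report.per_case[0]
        for region in ("WT", "TC", "ET"):
            assert report.region_means[region] == case[region]

    def test_empty_raises(self, tiny_model):
        with pytest.raises(ValueError):
            evaluate_dataset(tiny_model, [], TrainConfig())


class TestSplitDataset:
    def test_partition(self):
        data = list(range(10))
        train, val = split_dataset(data, 0.8, seed=0)
        assert len(train) == 8 and len(val) == 2
        assert sorted(train + val) == data

    def test_seed_determinism(self):
        data = list(range(20))
        assert split_dataset(data, 0.7, 5) == split_dataset(data, 0.7, 5)


class TestExportOverlay:
    def test_writes_nonempty_png(self, tmp_path, tiny_pair):
        stack, masks = tiny_pair
        out = tmp_path / "overlay.png"
        export_overlay(stack, masks, masks, slice_index=8, path=out)
        assert out.exists() and out.stat().st_size > 0

    def test_empty_masks_ok(self, tmp_path, tiny_pair):
        stack, masks = tiny_pair
        empty = MaskStack(data=np.zeros_like(masks.data), case_id="x")
        out = tmp_path / "empty.png"
        export_overlay(stack, empty, empty, slice_index=8, path=out)
        assert out.exists()

    def test_bad_slice_index_raises(self, tmp_path, tiny_pair):
        stack, masks = tiny_pair
        with pytest.raises(IndexError):
            export_overlay(stack, masks, masks, slice_index=99, path=tmp_path / "x.png")
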