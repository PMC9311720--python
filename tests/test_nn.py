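import numpy as np
import pytest

from spacerstrat.nn import (
    ConfigurationError,
    HDUNet,
    NetworkConfig,
    Tensor,
    TrainingConfig,
    TrainingError,
    loocv_folds,
    parameter,
    train,
)
from spacerstrat.nn import ops
from spacerstrat.preprocess import ModelInputTensor, NormalizationConstant


def directional_check(build_loss, arrays, eps=1e-2, rtol=2e-2):
    """Compare analytic gradients against a central finite difference along a
    random direction (float32 forward noise limits the attainable accuracy)."""
    rng = np.random.default_rng(0)
    tensors, loss = build_loss(arrays)
    loss.backward()
    for key, arr in arrays.items():
        d = rng.normal(size=arr.shape).astype(np.float32)
        plus = {k: (v + eps * d if k == key else v) for k, v in arrays.items()}
        minus = {k: (v - eps * d if k == key else v) for k, v in arrays.items()}
        fd = (float(build_loss(plus)[1].data) - float(build_loss(minus)[1].data)) / (2 * eps)
        analytic = float(np.sum(tensors[key].grad * d))
        assert analytic == pytest.approx(fd, rel=rtol, abs=1e-4), key


class TestOperatorGradients:
    def test_conv3d_gradients(self, rng):
        arrays = {
            "x": rng.normal(size=(2, 3, 4, 6, 6)).astype(np.float32),
            "w": (rng.normal(size=(2, 3, 3, 3, 3)) * 0.3).astype(np.float32),
            "b": rng.normal(size=2).astype(np.float32),
        }
        target = rng.normal(size=(2, 2, 4, 6, 6)).astype(np.float32)

        def build(a):
            t = {
                "x": Tensor(a["x"], requires_grad=True),
                "w": parameter(a["w"]),
                "b": parameter(a["b"]),
            }
            return t, ops.mse_loss(ops.conv3d(t["x"], t["w"], t["b"], 3), target)

        directional_check(build, arrays)

    def test_conv1x1_gradients(self, rng):
        arrays = {
            "x": rng.normal(size=(2, 4, 4, 4, 4)).astype(np.float32),
            "w": (rng.normal(size=(1, 4, 1, 1, 1)) * 0.3).astype(np.float32),
            "b": rng.normal(size=1).astype(np.float32),
        }
        target = rng.normal(size=(2, 1, 4, 4, 4)).astype(np.float32)

        def build(a):
            t = {
                "x": Tensor(a["x"], requires_grad=True),
                "w": parameter(a["w"]),
                "b": parameter(a["b"]),
            }
            return t, ops.mse_loss(ops.conv3d(t["x"], t["w"], t["b"], 1), target)

        directional_check(build, arrays)

    def test_pool_upsample_concat_chain_gradients(self, rng):
        arrays = {"x": rng.normal(size=(1, 2, 4, 4, 4)).astype(np.float32)}
        target = rng.normal(size=(1, 4, 4, 4, 4)).astype(np.float32)

        def build(a):
            xt = Tensor(a["x"], requires_grad=True)
            up = ops.upsample2(ops.maxpool2(xt))
            return {"x": xt}, ops.mse_loss(ops.concat([up, ops.relu(xt)]), target)

        directional_check(build, arrays)

    def test_upsample_doubles_each_spatial_dim(self, rng):
        x = Tensor(rng.normal(size=(1, 3, 2, 3, 4)).astype(np.float32))
        assert ops.upsample2(x).shape == (1, 3, 4, 6, 8)

    def test_upsample_preserves_constants(self):
        x = Tensor(np.full((1, 1, 2, 2, 2), 3.5, dtype=np.float32))
        np.testing.assert_allclose(ops.upsample2(x).data, 3.5)

    def test_maxpool_requires_even_dims(self, rng):
        with pytest.raises(ValueError):
            ops.maxpool2(Tensor(rng.normal(size=(1, 1, 3, 4, 4)).astype(np.float32)))


class TestNetworkContract:
    def test_forward_on_zero_input_is_finite_with_input_shape(self):
        cfg = NetworkConfig(levels=3, growth=2, convs_per_block=1)
        net = HDUNet(cfg, seed=0)
        out = net.predict(np.zeros((1, 5, 8, 8, 8), dtype=np.float32))
        assert out.shape == (1, 1, 8, 8, 8)
        assert np.all(np.isfinite(out))

    def test_full_scale_bottleneck_shape(self):
        """Five pooling levels reduce a 128 x 128 x 64 input to 8 x 8 x 4."""
        cfg = NetworkConfig.full_scale()
        z, y, x = cfg.bottleneck_shape((64, 128, 128))
        assert (x, y, z) == (8, 8, 4)

    def test_indivisible_shape_names_dimension(self):
        cfg = NetworkConfig(levels=4)
        with pytest.raises(ConfigurationError, match="z=20"):
            cfg.bottleneck_shape((20, 32, 32))

    def test_parameter_count_increases_with_growth(self):
        counts = [
            HDUNet(NetworkConfig(levels=3, growth=g), seed=0).n_parameters for g in (2, 4, 8)
        ]
        assert counts[0] < counts[1] < counts[2]

    def test_checkpoint_roundtrip_changes_nothing(self, rng):
        cfg = NetworkConfig(levels=2, growth=2, convs_per_block=1)
        a = HDUNet(cfg, seed=3)
        b = HDUNet(cfg, seed=4)
        x = rng.normal(size=(1, 5, 4, 4, 4)).astype(np.float32)
        b.load_state_arrays(a.state_arrays())
        np.testing.assert_array_equal(a.predict(x), b.predict(x))


def tiny_dataset(rng, n=2, shape=(8, 8, 8)):
    data = []
    for _ in range(n):
        channels = rng.random((5,) + shape) > 0.6
        tensor = ModelInputTensor(channels, (0, 0, 0), (3.0, 2.5, 2.5), (20, 20, 20))
        # target correlated with the input so there is something to learn
        target = (channels[1] * 0.8 + channels[3] * 0.1).astype(np.float32)
        data.append((tensor, target))
    return data


class TestTraining:
    def test_same_seed_reproduces_loss_history(self, rng):
        data = tiny_dataset(rng)
        cfg = NetworkConfig(levels=2, growth=2, convs_per_block=1)
        tc = TrainingConfig(learning_rate=1e-3, epochs=3, batch_size=2, seed=5)
        h1 = train(HDUNet(cfg, seed=1), data, tc, NormalizationConstant(70)).manifest["loss_history"]
        h2 = train(HDUNet(cfg, seed=1), data, tc, NormalizationConstant(70)).manifest["loss_history"]
        assert h1 == h2

    def test_capacity_overfits_two_samples(self, rng):
        data = tiny_dataset(rng)
        cfg = NetworkConfig(levels=2, growth=4, convs_per_block=2)
        tc = TrainingConfig(learning_rate=3e-3, epochs=200, batch_size=2, seed=0)
        model = train(HDUNet(cfg, seed=2), data, tc, NormalizationConstant(70))
        history = model.manifest["loss_history"]
        assert history[-1] < 0.1 * history[0]

    def test_overfit_model_recovers_rectal_dmean(self, rng):
        data = tiny_dataset(rng)
        cfg = NetworkConfig(levels=2, growth=4, convs_per_block=2)
        tc = TrainingConfig(learning_rate=3e-3, epochs=200, batch_size=2, seed=0)
        norm = NormalizationConstant(70.0)
        model = train(HDUNet(cfg, seed=2), data, tc, norm)
        tensor, target = data[0]
        pred = model.predict_dose(tensor)
        rectum = tensor.mask("rectum")
        truth_dmean = float((target * norm.max_dose_gy)[rectum].mean())
        assert float(pred.dose_gy[rectum].mean()) == pytest.approx(truth_dmean, abs=2.0)

    def test_prediction_is_clamped_non_negative(self, rng):
        data = tiny_dataset(rng, n=1)
        cfg = NetworkConfig(levels=2, growth=2, convs_per_block=1)
        net = HDUNet(cfg, seed=0)
        # force a strongly negative output bias
        net.final[1].data[:] = -10.0
        from spacerstrat.nn.training import TrainedModel

        model = TrainedModel(net, TrainingConfig(), NormalizationConstant(70.0))
        pred = model.predict_dose(data[0][0])
        assert pred.dose_gy.min() >= 0.0

    def test_nan_loss_aborts_with_diagnostic(self, rng):
        data = tiny_dataset(rng)
        bad = [(data[0][0], np.full_like(data[0][1], np.nan))]
        cfg = NetworkConfig(levels=2, growth=2, convs_per_block=1)
        with pytest.raises(TrainingError, match="epoch 0"):
            train(HDUNet(cfg, seed=0), bad, TrainingConfig(epochs=1, batch_size=1), NormalizationConstant(70))

    def test_empty_dataset_rejected(self):
        with pytest.raises(TrainingError):
            train(HDUNet(NetworkConfig(levels=2), seed=0), [], TrainingConfig(), NormalizationConstant(70))


class TestLOOCV:
    def test_three_patient_fold_arithmetic(self):
        plans = [p for p in ("a", "b", "c") for _ in range(6)]
        folds = loocv_folds(plans)
        assert len(folds) == 3
        assert all(len(f["train"]) == 12 and len(f["test"]) == 6 for f in folds)

    def test_twenty_patient_folds_train_on_114_plans(self):
        """19 remaining patients x 6 boost plans = 114 training plans per fold."""
        plans = [f"p{i:02d}" for i in range(20) for _ in range(6)]
        folds = loocv_folds(plans)
        assert len(folds) == 20
        assert all(len(f["train"]) == 114 for f in folds)

    def test_no_patient_leaks_into_training(self):
        plans = [p for p in ("a", "b", "c", "d") for _ in range(6)]
        folds = loocv_folds(plans)
        for fold in folds:
            held = fold["held_out"]
            assert all(plans[i] != held for i in fold["train"])
            assert all(plans[i] == held for i in fold["test"])

    def test_union_of_test_sets_covers_every_plan_once(self):
        plans = [p for p in ("a", "b", "c") for _ in range(6)]
        folds = loocv_folds(plans)
        covered = sorted(i for f in folds for i in f["test"])
        assert covered == list(range(len(plans)))

    def test_missing_boost_plans_rejected(self):
        plans = ["a"] * 6 + ["b"] * 4
        with pytest.raises(TrainingError, match="b"):
            loocv_folds(plans)

    def test_run_loocv_predicts_each_plan_exactly_once(self, rng):
        from spacerstrat.nn import run_loocv

        data = tiny_dataset(rng, n=4)
        patients = ["a", "a", "b", "b"]
        cfg = NetworkConfig(levels=2, growth=2, convs_per_block=1)
        tc = TrainingConfig(learning_rate=1e-3, epochs=1, batch_size=2, seed=0)
        result = run_loocv(data, patients, cfg, tc, NormalizationConstant(70.0))
        assert sorted(result["predictions"]) == [0, 1, 2, 3]
        assert [f["n_train"] for f in result["folds"]] == [2, 2]
        for dose in result["predictions"].values():
            assert dose.dose_gy.min() >= 0.0
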