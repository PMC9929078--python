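"""Network construction, the numpy CNN engine, and training behaviour."""

import numpy as np
import pytest

from cellcount import nn
from cellcount.datasets import Bank, LabeledImage
from cellcount.errors import ConfigurationError, ValidationError
from cellcount.model import (CountRegressor, ModelSpec, TrainConfig,
                             build_model, predict, spatial_chain, train)

from conftest import STUDY_SEEDS


def _bank(n, side, counts, seed=0, noise=True):
    rng = np.random.default_rng(seed)
    items = []
    for i in range(n):
        px = rng.random((side, side)).astype(np.float32) if noise \
            else np.full((side, side), 0.5, dtype=np.float32)
        items.append(LabeledImage(pixels=px, count=float(counts[i])))
    return Bank(items=items)


class TestSpatialChain:
    def test_default_input_follows_valid_conv_pool_recurrence(self):
        """Apply s -> (s - 2) // 2 per block by hand from 200."""
        expected, s = [], 200
        for _ in range(4):
            s = (s - 3 + 1) // 2
            expected.append(s)
        assert spatial_chain(200, 4) == expected == [99, 48, 23, 10]

    def test_too_small_input_names_failing_block(self):
        with pytest.raises(ConfigurationError, match="block"):
            spatial_chain(20, 4)

    def test_model_rejects_undersized_input(self):
        with pytest.raises(ConfigurationError):
            build_model(ModelSpec(input_size=(16, 16, 1)))


class TestBuildModel:
    def test_default_architecture_shape(self):
        m = build_model(ModelSpec(), seed=0)
        assert m.spatial_sizes == [99, 48, 23, 10]
        # 4 conv + 4 pool + flatten + dropout + dense
        assert len(m.net.layers) == 11

    def test_param_count_deterministic(self):
        a = build_model(ModelSpec(conv_blocks=(4, 8, 16, 32),
                                  input_size=(64, 64, 1)), seed=0)
        b = build_model(ModelSpec(conv_blocks=(4, 8, 16, 32),
                                  input_size=(64, 64, 1)), seed=0)
        assert a.n_params() == b.n_params()
        for pa, pb in zip(a.net.params(), b.net.params()):
            np.testing.assert_array_equal(pa, pb)

    def test_zero_input_prediction_is_relu_of_bias(self):
        m = build_model(ModelSpec(conv_blocks=(4, 8, 16, 32),
                                  input_size=(64, 64, 1)), seed=1)
        x = np.zeros((2, 64, 64, 1), dtype=np.float32)
        out = m.forward_counts(x)
        assert (out >= 0).all()
        np.testing.assert_allclose(out, max(0.0, m.net.layers[-1].b[0]), atol=1e-6)

    def test_zero_dropout_is_identity_at_train_time(self):
        rng = np.random.default_rng(0)
        layer = nn.Dropout(0.0, rng)
        x = rng.random((4, 7)).astype(np.float32)
        np.testing.assert_array_equal(layer.forward(x, train=True), x)


class TestEngineGradients:
    def test_backward_matches_finite_differences(self):
        """Numeric gradient check of the full conv/pool/dense stack."""
        rng = np.random.default_rng(0)
        net = nn.Sequential([
            nn.Conv2D(1, 2, 3, rng),
            nn.MaxPool2(),
            nn.Flatten(),
            nn.Dense(2 * 4 * 4, 1, rng),
        ])
        # run the check in float64 so central differences are trustworthy
        for layer in net.layers:
            if layer.params():
                layer.W = layer.W.astype(np.float64)
                layer.b = layer.b.astype(np.float64)
                layer.dW = np.zeros_like(layer.W)
                layer.db = np.zeros_like(layer.b)
        x = rng.random((3, 10, 10, 1))
        y = rng.random(3)

        def loss():
            pred = net.forward(x, train=True)[:, 0]
            return float(np.mean((pred - y) ** 2))

        resid = net.forward(x, train=True)[:, 0] - y
        net.backward((2 * resid / len(y))[:, None])
        eps = 1e-5
        check = 0
        for p, g in zip(net.params(), net.grads()):
            flat_p, flat_g = p.ravel(), g.ravel()
            for k in range(0, flat_p.size, max(1, flat_p.size // 5)):
                orig = flat_p[k]
                flat_p[k] = orig + eps
                up = loss()
                flat_p[k] = orig - eps
                down = loss()
                flat_p[k] = orig
                numeric = (up - down) / (2 * eps)
                assert numeric == pytest.approx(flat_g[k], rel=1e-4, abs=1e-7)
                check += 1
        assert check >= 15

    def test_relu_output_nonnegative(self):
        rng = np.random.default_rng(2)
        m = build_model(ModelSpec(conv_blocks=(2, 2, 4, 4),
                                  input_size=(48, 48, 1)), seed=3)
        x = rng.random((8, 48, 48, 1)).astype(np.float32)
        assert (m.forward_counts(x) >= 0).all()


class TestTraining:
    def test_constant_count_bank_fits_to_near_zero(self):
        counts = [40.0] * 20
        bank = _bank(20, 48, counts, noise=False)
        m = build_model(ModelSpec(conv_blocks=(2, 2, 4, 4),
                                  input_size=(48, 48, 1)), seed=0)
        hist = train(m, bank, bank, TrainConfig(max_epochs=30, patience=30, seed=0))
        assert min(hist.val_mse) <= 0.01 * 40.0**2

    def test_shuffled_labels_stop_early(self):
        rng = np.random.default_rng(1)
        counts = rng.permutation(np.linspace(10, 200, 30))
        bank = _bank(30, 48, counts, noise=True)
        m = build_model(ModelSpec(conv_blocks=(2, 2, 4, 4),
                                  input_size=(48, 48, 1)), seed=0)
        cfg = TrainConfig(max_epochs=200, patience=5, seed=0)
        hist = train(m, bank, bank, cfg)
        assert hist.stopped_epoch < cfg.max_epochs / 2
        assert len(hist.train_mse) == len(hist.val_mse) == hist.stopped_epoch

    def test_history_lengths_and_best_epoch(self):
        bank = _bank(10, 48, np.linspace(5, 50, 10))
        m = build_model(ModelSpec(conv_blocks=(2, 2, 4, 4),
                                  input_size=(48, 48, 1)), seed=0)
        hist = train(m, bank, bank, TrainConfig(max_epochs=8, patience=8, seed=0))
        assert hist.stopped_epoch == 8
        assert 1 <= hist.best_epoch <= 8
        # restore-best: reported predictions reproduce the best validation MSE
        preds = predict(m, bank)
        np.testing.assert_allclose(np.mean((preds - bank.counts())**2),
                                   min(hist.val_mse), rtol=1e-5)

    def test_predict_requires_training(self):
        m = build_model(ModelSpec(conv_blocks=(2, 2, 4, 4),
                                  input_size=(48, 48, 1)))
        with pytest.raises(ValidationError):
            predict(m, _bank(3, 48, [1, 2, 3]))

    def test_shape_mismatch_rejected(self):
        m = build_model(ModelSpec(conv_blocks=(2, 2, 4, 4),
                                  input_size=(48, 48, 1)))
        with pytest.raises(ValidationError):
            train(m, _bank(4, 32, [1, 2, 3, 4]), _bank(4, 32, [1, 2, 3, 4]),
                  TrainConfig(max_epochs=1, patience=1))


@pytest.fixture(scope="module")
def trained():
    counts = np.linspace(10, 90, 16)
    bank = _bank(16, 48, counts)
    m = build_model(ModelSpec(conv_blocks=(2, 2, 4, 4),
                              input_size=(48, 48, 1)), seed=0)
    train(m, bank, bank, TrainConfig(max_epochs=3, patience=3, seed=0))
    return m, bank


class TestInference:

    def test_duplicates_get_identical_predictions(self, trained):
        m, bank = trained
        dup = Bank(items=[bank.items[0], bank.items[0], bank.items[3]])
        preds = predict(m, dup)
        assert preds[0] == preds[1]

    def test_batched_equals_single_image_prediction(self, trained):
        m, bank = trained
        batched = predict(m, bank)
        singles = np.concatenate(
            [predict(m, Bank(items=[im])) for im in bank.items])
        np.testing.assert_allclose(batched, singles, rtol=1e-5, atol=1e-5)


class TestContrastDegradation:
    def test_low_contrast_recovery_is_worse_across_seeds(self, study_runs):
        """With identical architecture, seeds and bank sizes, held-out Pearson R
        collapses when cell intensity matches the background."""
        for seed in STUDY_SEEDS:
            r_high = study_runs[("high", seed)].report.pearson_r
            r_low = study_runs[("low", seed)].report.pearson_r
            assert r_low < r_high


class TestSerialization:
    def test_model_round_trip(self, trained, tmp_path):
        m, bank = trained
        path = str(tmp_path / "model.npz")
        m.save(path)
        back = CountRegressor.load(path)
        np.testing.assert_array_equal(predict(back, bank), predict(m, bank))
        assert back.output_scale == m.output_scale

    def test_history_files(self, trained, tmp_path):
        bank = trained[1]
        m = build_model(ModelSpec(conv_blocks=(2, 2, 4, 4),
                                  input_size=(48, 48, 1)), seed=1)
        hist = train(m, bank, bank, TrainConfig(max_epochs=4, patience=4, seed=1))
        hist.save(str(tmp_path))
        lines = open(tmp_path / "history.csv").read().splitlines()
        assert lines[0] == "epoch,train_mse,val_mse"
        assert len(lines) == 1 + hist.stopped_epoch
        import json
        summary = json.load(open(tmp_path / "summary.json"))
        assert summary["stopped_epoch"] == hist.stopped_epoch
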