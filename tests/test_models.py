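"""Classifier architectures, forward passes, and training behavior."""

import numpy as np
import pytest

from voicedx.models import (
    ModelConfig, TrainConfig, UnsupportedModelError, UtteranceFeatures,
    build_model, extract_hidden_features, forward_frames, load_model,
    n_parameters, save_model, train_model,
)
from oracles import bilstm_head_reference, lstm_reference


def _toy_data(rng, n_classes=3, n_utts=30, T=20, sep=6.0, dim=26):
    data = []
    for cls in range(n_classes):
        mu = np.zeros(dim)
        mu[cls] = sep
        for u in range(n_utts):
            data.append(UtteranceFeatures(
                (rng.normal(size=(T, dim)) + mu).astype(np.float32),
                cls, f"s{cls}-{u}"))
    return data


class TestArchitectures:
    def test_dnn_parameter_count(self):
        model = build_model(ModelConfig(kind="dnn", n_classes=4))
        assert n_parameters(model) == 86604  # 26*200+200 + 2*(200*200+200) + 200*4+4

    def test_rf_ensemble_size(self):
        model = build_model(ModelConfig(kind="rf", n_classes=4))
        assert model.forest.n_estimators == 26

    def test_bilstm_hidden_width_is_cell_count(self):
        model = build_model(ModelConfig(kind="bilstm", n_classes=4))
        x = np.random.default_rng(0).normal(size=(7, 26)).astype(np.float32)
        frames, pooled = extract_hidden_features(model, x)
        assert frames.shape == (7, 50) and pooled.shape == (50,)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(kind="cnn")

    def test_learning_rate_defaults(self):
        tc = TrainConfig()
        assert tc.lr_for("dnn") == tc.lr_for("gru") == 1e-3
        assert tc.lr_for("lstm") == tc.lr_for("bilstm") == 5e-4


class TestForward:
    @pytest.mark.parametrize("kind", ["dnn", "lstm", "bilstm", "gru"])
    def test_zero_weights_give_uniform_posteriors(self, kind):
        model = build_model(ModelConfig(kind=kind, n_classes=4))
        for p in model.parameters():
            p.value[...] = 0.0
        probs = forward_frames(model, np.random.default_rng(0)
                               .normal(size=(5, 26)))
        np.testing.assert_allclose(probs, 0.25, atol=1e-7)

    @pytest.mark.parametrize("kind", ["dnn", "lstm", "bilstm", "gru"])
    def test_rows_are_distributions(self, kind):
        model = build_model(ModelConfig(kind=kind, n_classes=4), seed=2)
        probs = forward_frames(model, np.random.default_rng(1)
                               .normal(size=(9, 26)))
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_dimension_mismatch_raises(self):
        model = build_model(ModelConfig(kind="dnn", n_classes=4))
        with pytest.raises(ValueError):
            forward_frames(model, np.zeros((4, 13)))

    def test_bilstm_matches_gate_equation_oracle(self):
        """Random small instances (<=5 frames, <=3 cells) against the
        hand-rolled forward/backward LSTM recursion."""
        for trial in range(10):
            r = np.random.default_rng(100 + trial)
            T, H = int(r.integers(1, 6)), int(r.integers(1, 4))
            cfg = ModelConfig(kind="bilstm", n_classes=3, n_layers=1,
                              cells=H, dropout=0.0)
            model = build_model(cfg, input_dim=4, seed=trial)
            x = r.normal(size=(T, 4)).astype(np.float32)
            blk = model.blocks[0]
            ref = bilstm_head_reference(
                x.astype(float),
                (blk.fwd.Wx.value.astype(float), blk.fwd.Wh.value.astype(float),
                 blk.fwd.b.value.astype(float)),
                (blk.bwd.Wx.value.astype(float), blk.bwd.Wh.value.astype(float),
                 blk.bwd.b.value.astype(float)),
                model.head.W.value.astype(float),
                model.head.b.value.astype(float))
            np.testing.assert_allclose(forward_frames(model, x), ref, atol=1e-6)

    def test_bilstm_direction_swap_symmetry(self):
        """Reversing the input and swapping the directional weights reverses
        the per-frame outputs."""
        cfg = ModelConfig(kind="bilstm", n_classes=3, n_layers=1, cells=4,
                          dropout=0.0)
        model = build_model(cfg, input_dim=5, seed=0)
        x = np.random.default_rng(3).normal(size=(6, 5)).astype(np.float32)
        y1 = forward_frames(model, x)
        blk = model.blocks[0]
        for name in ("Wx", "Wh", "b"):
            a, b = getattr(blk.fwd, name), getattr(blk.bwd, name)
            a.value, b.value = b.value, a.value
        y2 = forward_frames(model, x[::-1].copy())
        np.testing.assert_allclose(y2, y1[::-1], atol=1e-6)

    def test_lstm_layer_matches_reference_recursion(self):
        cfg = ModelConfig(kind="lstm", n_classes=3, n_layers=1, cells=3,
                          dropout=0.0)
        model = build_model(cfg, input_dim=4, seed=5)
        x = np.random.default_rng(6).normal(size=(5, 4)).astype(np.float32)
        frames, _ = extract_hidden_features(model, x)
        layer = model.blocks[0]
        ref = lstm_reference(x.astype(float), layer.Wx.value.astype(float),
                             layer.Wh.value.astype(float),
                             layer.b.value.astype(float))
        np.testing.assert_allclose(frames, ref, atol=1e-6)

    def test_rf_frame_order_invariance(self):
        rng = np.random.default_rng(7)
        data = _toy_data(rng, n_utts=5, T=10)
        model = build_model(ModelConfig(kind="rf", n_classes=3), seed=0)
        train_model(model, data, TrainConfig(seed=0))
        x = data[0].mfcc
        perm = rng.permutation(x.shape[0])
        p1 = forward_frames(model, x)
        p2 = forward_frames(model, x[perm])
        np.testing.assert_allclose(p2, p1[perm])


class TestTraining:
    def test_separable_classes_reach_high_frame_accuracy(self):
        rng = np.random.default_rng(0)
        data = _toy_data(rng, n_classes=4, n_utts=25)  # 100 utterances
        model = build_model(ModelConfig(kind="dnn", n_classes=4), seed=0)
        train_model(model, data, TrainConfig(epochs=30, seed=0))
        frames = np.vstack([d.mfcc for d in data])
        labels = np.concatenate([[d.label] * d.mfcc.shape[0] for d in data])
        acc = (forward_frames(model, frames).argmax(axis=1) == labels).mean()
        assert acc >= 0.99

    def test_loss_non_increasing_early(self):
        rng = np.random.default_rng(1)
        data = _toy_data(rng)
        model = build_model(ModelConfig(kind="dnn", n_classes=3), seed=1)
        res = train_model(model, data, TrainConfig(epochs=5, seed=1))
        assert np.all(np.diff(res.epoch_losses) <= 1e-9)

    def test_same_seed_identical_final_loss(self):
        rng = np.random.default_rng(2)
        data = _toy_data(rng, n_utts=8, T=10)
        losses = []
        for _ in range(2):
            model = build_model(ModelConfig(kind="gru", n_classes=3,
                                            cells=8), seed=4)
            res = train_model(model, data, TrainConfig(epochs=3, seed=4))
            losses.append(res.epoch_losses[-1])
        assert losses[0] == losses[1]

    def test_single_class_data_rejected(self):
        rng = np.random.default_rng(3)
        data = [UtteranceFeatures(rng.normal(size=(5, 26)).astype(np.float32),
                                  1, None) for _ in range(4)]
        model = build_model(ModelConfig(kind="dnn", n_classes=4))
        with pytest.raises(ValueError):
            train_model(model, data, TrainConfig())

    def test_crossval_returns_fold_uars(self):
        from voicedx.models import crossval_uar

        rng = np.random.default_rng(4)
        data = _toy_data(rng, n_utts=10, T=8)
        uars = crossval_uar(ModelConfig(kind="dnn", n_classes=3), data,
                            TrainConfig(epochs=5, seed=0, folds=5))
        assert len(uars) == 5
        assert all(0.0 <= u <= 100.0 for u in uars)


class TestHiddenFeatures:
    def test_single_frame_pooled_equals_frame(self):
        model = build_model(ModelConfig(kind="gru", n_classes=4), seed=1)
        x = np.random.default_rng(0).normal(size=(1, 26)).astype(np.float32)
        frames, pooled = extract_hidden_features(model, x)
        np.testing.assert_allclose(pooled, frames[0])

    def test_zero_weight_model_zero_activations(self):
        model = build_model(ModelConfig(kind="bilstm", n_classes=4))
        for p in model.parameters():
            p.value[...] = 0.0
        frames, pooled = extract_hidden_features(
            model, np.random.default_rng(0).normal(size=(4, 26)))
        np.testing.assert_allclose(frames, 0.0)
        np.testing.assert_allclose(pooled, 0.0)

    @pytest.mark.parametrize("kind", ["dnn", "rf"])
    def test_static_models_unsupported(self, kind):
        model = build_model(ModelConfig(kind=kind, n_classes=4))
        with pytest.raises(UnsupportedModelError):
            extract_hidden_features(model, np.zeros((3, 26)))


class TestCheckpoints:
    def test_neural_roundtrip(self, tmp_path):
        rng = np.random.default_rng(5)
        data = _toy_data(rng, n_utts=6, T=8)
        model = build_model(ModelConfig(kind="lstm", n_classes=3, cells=6),
                            seed=2)
        train_model(model, data, TrainConfig(epochs=2, seed=2))
        path = tmp_path / "model.npz"
        save_model(path, model)
        loaded = load_model(path)
        x = data[0].mfcc
        np.testing.assert_allclose(forward_frames(loaded, x),
                                   forward_frames(model, x), atol=1e-7)
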