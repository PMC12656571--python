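import numpy as np
import pytest

import imubreath as ib
from imubreath import nn
from imubreath.core_io import CODE_BREATHING, CODE_NOISE
from imubreath.crnn_model import ModelSpec, TrainConfig
from imubreath.errors import ConfigError, DegenerateDataError
from imubreath.windowing import WindowSet


def _window_set(x, y, w=None):
    n = len(x)
    return WindowSet(
        windows=np.asarray(x, dtype=float),
        labels=np.asarray(y, dtype=np.int8),
        subject_ids=np.array(["A"] * n, dtype=object),
        start_indices=np.arange(n, dtype=np.int64),
        window_size=w or x.shape[1],
        step=1,
        sampling_rate_hz=10.0,
    )


TINY = ModelSpec(
    in_channels=3, conv1_filters=2, conv2_filters=3, lstm_units=4,
    dense_units=3, dropout_p=0.0, window_size=20,
)


def _separable_toy(n=96, w=24, c=3, seed=0):
    """Sinusoid vs. white noise windows: trivially separable."""
    rng = np.random.default_rng(seed)
    t = np.arange(w)
    x, y = [], []
    for i in range(n):
        if i % 2:
            base = np.sin(2 * np.pi * t / 8 + rng.uniform(0, 2 * np.pi))
            x.append(np.outer(base, np.ones(c)) + 0.05 * rng.standard_normal((w, c)))
            y.append(CODE_BREATHING)
        else:
            x.append(rng.standard_normal((w, c)))
            y.append(CODE_NOISE)
    return np.array(x), np.array(y)


class TestParameterCount:
    def test_default_architecture(self):
        assert ib.count_trainable_parameters(ModelSpec()) == 47_713

    def test_layer_contributions(self):
        spec = ModelSpec()
        assert (spec.in_channels * spec.conv1_kernel + 1) * spec.conv1_filters == 2_272
        lstm = 4 * ((spec.conv2_filters + spec.lstm_units) * spec.lstm_units + spec.lstm_units)
        assert lstm == 33_024

    def test_independent_of_window_size(self):
        assert ib.count_trainable_parameters(ModelSpec(window_size=500)) == ib.count_trainable_parameters(
            ModelSpec(window_size=2000)
        )

    @pytest.mark.parametrize("spec", [ModelSpec(window_size=100), TINY,
                                      ModelSpec(conv1_filters=8, lstm_units=16, window_size=64)])
    def test_closed_form_matches_brute_force_tally(self, spec):
        net = ib.build_model(spec, seed=0)
        assert net.n_parameters() == ib.count_trainable_parameters(spec)

    def test_memory_footprint(self):
        assert round(ib.memory_footprint_mb(ModelSpec()), 2) == 0.18

    def test_too_small_window_rejected(self):
        with pytest.raises(ConfigError):
            ib.build_model(ModelSpec(window_size=10), seed=0)

    def test_lstm_input_length_for_best_window(self):
        # valid convs + pool 2 twice: 2000 -> 1996 -> 998 -> 994 -> 497
        assert ModelSpec(window_size=2000).sequence_lengths() == (1996, 998, 994, 497)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        net = ib.build_model(TINY, seed=1)
        rng = np.random.default_rng(2)
        x = rng.standard_normal((4, TINY.window_size, TINY.in_channels))
        y = rng.integers(0, 2, 4).astype(float)
        w = rng.uniform(0.5, 2.0, 4)
        net.zero_grad()
        loss, dlogits = nn.bce_with_logits(net.forward(x, train=False), y, w)
        net.backward(dlogits)
        eps = 1e-6
        for p in net.params():
            flat, grad = p.value.ravel(), p.grad.ravel()
            for k in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[k]
                flat[k] = orig + eps
                lp, _ = nn.bce_with_logits(net.forward(x, train=False), y, w)
                flat[k] = orig - eps
                lm, _ = nn.bce_with_logits(net.forward(x, train=False), y, w)
                flat[k] = orig
                num = (lp - lm) / (2 * eps)
                assert grad[k] == pytest.approx(num, rel=1e-4, abs=1e-8), p.name


class TestTraining:
    def test_learning_reduces_loss(self):
        x, y = _separable_toy()
        net = ib.build_model(TINY, seed=3)
        cfg = TrainConfig(epochs=5, batch_size=16, seed=3)
        model = ib.train(net, _window_set(x, y), None, cfg, spec=TINY)
        hist = model.history["train_loss"]
        assert hist[-1] < hist[0]

    def test_deterministic_history_for_fixed_seed(self):
        x, y = _separable_toy()
        h = []
        for _ in range(2):
            net = ib.build_model(TINY, seed=4)
            model = ib.train(net, _window_set(x, y), None,
                             TrainConfig(epochs=2, batch_size=16, seed=4), spec=TINY)
            h.append(model.history["train_loss"])
        assert h[0] == h[1]

    def test_unit_class_weights_equal_unweighted(self):
        x, y = _separable_toy()
        cw = ib.compute_class_weights(48, 48)  # balanced -> weights (1, 1)
        assert (cw.weight_breathing, cw.weight_noise) == (1.0, 1.0)
        hists = []
        for weights in (None, cw):
            net = ib.build_model(TINY, seed=5)
            model = ib.train(net, _window_set(x, y), None,
                             TrainConfig(epochs=2, batch_size=16, class_weights=weights, seed=5),
                             spec=TINY)
            hists.append(model.history["train_loss"])
        assert hists[0] == hists[1]

    def test_shuffled_labels_give_chance_level_validation_loss(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((128, TINY.window_size, TINY.in_channels))
        y = rng.integers(0, 2, 128)  # labels carry no signal
        xv = rng.standard_normal((64, TINY.window_size, TINY.in_channels))
        yv = rng.integers(0, 2, 64)
        net = ib.build_model(TINY, seed=6)
        model = ib.train(net, _window_set(x, y), _window_set(xv, yv),
                         TrainConfig(epochs=3, batch_size=16, seed=6), spec=TINY)
        assert model.history["val_loss"][-1] == pytest.approx(np.log(2), abs=0.1)

    def test_single_class_training_set_rejected(self):
        x, _ = _separable_toy()
        y = np.ones(len(x), dtype=np.int8)
        net = ib.build_model(TINY, seed=7)
        with pytest.raises(DegenerateDataError):
            ib.train(net, _window_set(x, y), None, TrainConfig(epochs=1, seed=7))


class TestPrediction:
    def test_probabilities_in_unit_interval(self):
        net = ib.build_model(TINY, seed=8)
        x = np.random.default_rng(8).standard_normal((10, TINY.window_size, TINY.in_channels))
        p = ib.predict_proba(net, x)
        assert np.all((p >= 0.0) & (p <= 1.0))

    def test_batching_invariance(self):
        net = ib.build_model(TINY, seed=9)
        x = np.random.default_rng(9).standard_normal((64, TINY.window_size, TINY.in_channels))
        p_one = ib.predict_proba(net, x, batch_size=64)
        p_two = ib.predict_proba(net, x, batch_size=32)
        p_each = ib.predict_proba(net, x, batch_size=1)
        np.testing.assert_allclose(p_one, p_two, rtol=0, atol=1e-12)
        np.testing.assert_allclose(p_one, p_each, rtol=0, atol=1e-12)

    def test_channel_mismatch_rejected(self):
        net = ib.build_model(TINY, seed=10)
        with pytest.raises(ValueError, match="windows"):
            ib.predict_proba(net, np.zeros((2, TINY.window_size, 5)))

    def test_trained_model_scores_breathing_high(self, trained_small_model, small_cfg):
        spec = ib.SyntheticSpec(
            duration_s=30.0, sampling_rate_hz=33.0,
            breathing_spans=[(0.0, 30.0)], noise_episodes=[], seed=77,
        )
        rec, _ = ib.simulate_recording(spec)
        fs = ib.engineer_features(rec)
        ws = ib.make_windows(fs, ib.AnnotationTrack([]), small_cfg)
        x = ib.apply_norm(ws.windows, trained_small_model.norm_stats)
        p = ib.predict_proba(trained_small_model, x)
        assert np.mean(p > 0.5) > 0.9


class TestBundle:
    def test_save_load_roundtrip_preserves_predictions(self, tmp_path):
        x, y = _separable_toy()
        net = ib.build_model(TINY, seed=11)
        model = ib.train(net, _window_set(x, y), None,
                         TrainConfig(epochs=1, batch_size=16, seed=11), spec=TINY)
        ib.save_bundle(model, tmp_path / "bundle")
        back = ib.load_bundle(tmp_path / "bundle")
        np.testing.assert_allclose(
            ib.predict_proba(back, x), ib.predict_proba(model, x), atol=1e-12
        )
        assert back.spec == TINY
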