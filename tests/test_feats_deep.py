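import numpy as np
import pytest

from neurochoice.feats_deep import (LeNetSpec, TrainingConfig,
                                    build_cnn_lstm, build_lenet5,
                                    extract_features, prepare_eeg_input,
                                    prepare_gaze_input, train_extractor)
from neurochoice.nnet import (LSTM, Adam, BuildError, Conv2D, Dense, Flatten,
                              MaxPool2D, Param, Reshape, Sequential)
from neurochoice.synthgen import (ArtifactRates, ClassEffect, SynthConfig,
                                  generate_et_trial)
from neurochoice.gaze_prep import GazeConfig, render_gaze_plot, segment_et


class TestArchitectureTables:
    def test_cnn_lstm_layer_table(self):
        table = {name: (shape, n) for name, shape, n in
                 build_cnn_lstm().layer_table()}
        assert table["input"][0] == (None, 19, 300, 1)
        assert table["conv1"] == ((None, 17, 298, 32), 320)
        assert table["pool1"][0] == (None, 8, 149, 32)
        assert table["conv2"] == ((None, 6, 147, 64), 18496)
        assert table["pool2"][0] == (None, 3, 73, 64)
        assert table["flatten"][0] == (None, 14016)
        assert table["reshape"][0] == (None, 14016, 1)
        assert table["lstm"][0] == (None, 64)
        assert table["dense_128"] == ((None, 128), 8320)
        assert table["dense_64"] == ((None, 64), 8256)

    def test_lstm_param_count_is_standard(self):
        # 4·64·(1 + 64 + 1): the standard cell, not the printed 16,832
        table = {name: n for name, _, n in build_cnn_lstm().layer_table()}
        assert table["lstm"] == 4 * 64 * (1 + 64 + 1) == 16896

    def test_lenet_layer_table(self):
        table = {name: (shape, n) for name, shape, n in
                 build_lenet5().layer_table()}
        assert table["input"][0] == (None, 64, 64, 1)
        assert table["conv1"][0] == (None, 60, 60, 6)
        assert table["conv1"][1] == 6 * (5 * 5 * 1 + 1) == 156
        assert table["pool1"][0] == (None, 30, 30, 6)
        assert table["conv2"] == ((None, 26, 26, 16), 2416)
        assert table["pool2"][0] == (None, 13, 13, 16)
        assert table["flatten"][0] == (None, 2704)
        assert table["dense_120"][0] == (None, 120)
        assert table["dense_84"][0] == (None, 84)

    def test_wrong_canvas_rejected(self):
        with pytest.raises(BuildError):
            build_lenet5(LeNetSpec(input_shape=(32, 32, 1)))

    def test_kernel_too_large_rejected(self):
        with pytest.raises(BuildError):
            Sequential((3, 3, 1), [Conv2D(2, 5, name="c")], seed=0)


class TestFeatureExtraction:
    def test_extraction_widths(self, rng):
        cnn = build_cnn_lstm(seed=0)
        X = rng.normal(size=(3, 19, 300, 1)).astype(np.float32)
        assert extract_features(cnn, X, "flatten").shape == (3, 14016)
        assert extract_features(cnn, X, "last_dense").shape == (3, 64)
        lenet = build_lenet5(seed=0)
        G = rng.random((3, 64, 64, 1)).astype(np.float32)
        assert extract_features(lenet, G, "flatten").shape == (3, 2704)
        assert extract_features(lenet, G, "last_dense").shape == (3, 84)

    def test_unknown_layer_rejected(self, rng):
        with pytest.raises(KeyError):
            extract_features(build_lenet5(), rng.random((1, 64, 64, 1)), "conv9")

    def test_zero_input_finite_features(self):
        lenet = build_lenet5(seed=1)
        f = extract_features(lenet, np.zeros((2, 64, 64, 1)), "flatten")
        assert np.isfinite(f).all()

    def test_extraction_deterministic(self, rng):
        lenet = build_lenet5(seed=3)
        X = rng.random((4, 64, 64, 1)).astype(np.float32)
        np.testing.assert_array_equal(extract_features(lenet, X, "last_dense"),
                                      extract_features(lenet, X, "last_dense"))


class TestGradientsAndAdam:
    def test_tiny_network_gradients_match_finite_differences(self, rng):
        net = Sequential((6, 8, 1), [
            Conv2D(3, 3, name="c1"), MaxPool2D(name="p1"),
            Flatten(name="f"), Reshape((18, 1), name="r"), LSTM(5, name="l"),
            Dense(4, "relu", name="d1"), Dense(1, None, name="head")], seed=1)
        X = rng.normal(size=(4, 6, 8, 1))
        y = np.array([0.0, 1.0, 1.0, 0.0])

        def loss():
            z = net.forward(X).ravel()
            p = 1 / (1 + np.exp(-z))
            return float(((y - p) ** 2).mean())

        z = net._forward_chunk(X.astype(np.float32), None, True).ravel()
        p = 1 / (1 + np.exp(-z))
        g = (2 * (p - y) / len(y) * p * (1 - p)).reshape(-1, 1).astype(np.float32)
        for layer in reversed(net.layers):
            g = layer.backward(g)
        for prm in (p for l in net.layers for p in l.params()):
            flat, gflat = prm.value.ravel(), prm.grad.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                old, eps = flat[i], 1e-3
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - gflat[i]) < 1e-3 * max(1.0, abs(num))

    def test_adam_update_matches_hand_formula(self):
        cfg = TrainingConfig(learning_rate=0.1, beta1=0.9, beta2=0.999,
                             epsilon=1e-8, seed=0)
        p = Param(np.array([1.0]))
        p.grad[:] = 0.5
        opt = Adam([p], cfg)
        opt.step()
        m = 0.1 * 0.5
        v = 0.001 * 0.25
        expected = 1.0 - 0.1 * (m / 0.1) / (np.sqrt(v / 0.001) + 1e-8)
        assert p.value[0] == pytest.approx(expected, rel=1e-6)

    def test_zero_learning_rate_freezes_parameters(self, rng):
        lenet = build_lenet5(seed=2)
        before = [p.value.copy() for l in lenet.layers for p in l.params()]
        X = rng.random((8, 64, 64, 1)).astype(np.float32)
        y = np.array([0, 1] * 4)
        train_extractor(lenet, X, y,
                        TrainingConfig(loss="bce", epochs=2, learning_rate=0.0))
        after = [p.value for l in lenet.layers for p in l.params()]
        for a, b in zip(before, after):
            np.testing.assert_array_equal(a, b)


def _strong_gaze_plots(n_per_class, seed):
    eff = ClassEffect(alpha_power_ratio=1.0, fixation_duration_shift=200.0,
                      saccade_amplitude_shift=50.0)
    cfg = SynthConfig(n_subjects=1, trials_per_subject=2, trial_duration=1.0,
                      class_effect=eff, artifact_rates=ArtifactRates(0, 0, 0),
                      seed=seed)
    rng = np.random.default_rng(seed)
    plots, labels = [], []
    for label in (0, 1):
        for _ in range(n_per_class):
            rec = generate_et_trial(cfg, label, rng)
            w, _, _, _ = segment_et(rec, GazeConfig())
            plots.append(render_gaze_plot(w[0], cfg.screen_size))
            labels.append(label)
    return prepare_gaze_input(plots), np.array(labels)


class TestTrainingContract:
    def test_lenet_loss_decreases_on_structured_data(self):
        """Training loss falls over the first epochs for most seeds when the
        gaze plots carry class structure."""
        ok = 0
        for seed in range(5):
            X, y = _strong_gaze_plots(30, seed)
            model = build_lenet5(seed=seed)
            hist = train_extractor(
                model, X, y, TrainingConfig(loss="bce", epochs=5, seed=seed))
            if hist[-1] < hist[0]:
                ok += 1
        assert ok >= 4

    def test_cnn_lstm_trains_and_loss_decreases(self, rng):
        X = rng.normal(size=(24, 19, 300, 1)).astype(np.float32)
        y = np.repeat([0, 1], 12)
        # give class 1 an obvious amplitude signature
        X[y == 1] *= 2.0
        model = build_cnn_lstm(seed=0)
        hist = train_extractor(model, prepare_eeg_input(X[:, :, :, 0]), y,
                               TrainingConfig(loss="mse", epochs=3, seed=0))
        assert hist[-1] < hist[0]

    def test_single_class_labels_rejected(self, rng):
        model = build_lenet5(seed=0)
        with pytest.raises(ValueError):
            train_extractor(model, rng.random((6, 64, 64, 1)),
                            np.ones(6), TrainingConfig(epochs=1))

    def test_training_deterministic_under_seed(self, rng):
        X = rng.random((12, 64, 64, 1)).astype(np.float32)
        y = np.array([0, 1] * 6)
        weights = []
        for _ in range(2):
            m = build_lenet5(seed=9)
            train_extractor(m, X, y, TrainingConfig(loss="bce", epochs=2, seed=9))
            weights.append(np.concatenate(
                [p.value.ravel() for l in m.layers for p in l.params()]))
        np.testing.assert_array_equal(weights[0], weights[1])
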