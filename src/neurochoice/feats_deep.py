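"""Deep feature extractors: a CNN-LSTM for EEG windows and a LeNet-5 for
64×64 gaze-plot images.

Both networks are trained as supervised binary classifiers on the window
label (buy / no-buy) through a 1-unit sigmoid head; the head is then ignored
and an internal layer's activations serve as the feature vector. The default
extraction layer is the convolutional flatten (14,016 dims for EEG, 2,704 for
gaze plots — their concatenation is the 16,720-dim fused deep vector); the
``last_dense`` option (64 / 84 dims) gives a compact alternative that is far
cheaper for downstream ensembles.

Two printed-reference discrepancies are deliberate: the standard LSTM
parameter count for a 64-unit cell on 1-dim input is 4·64·(1+64+1) = 16,896,
and a 5×5 convolution with 6 filters over a 1-channel image has 156
parameters. (Counts of 16,832 and 456 would require a non-standard cell and a
3-channel input, respectively, and are not reproduced.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nnet import (LSTM, BuildError, Conv2D, Dense, Flatten, MaxPool2D,
                   Reshape, Sequential, TrainingConfig)

__all__ = ["CNNLSTMSpec", "LeNetSpec", "TrainingConfig", "build_cnn_lstm",
           "build_lenet5", "train_extractor", "extract_features",
           "prepare_eeg_input", "prepare_gaze_input"]


@dataclass(frozen=True)
class CNNLSTMSpec:
    input_shape: tuple = (19, 300, 1)
    conv1_filters: int = 32
    conv2_filters: int = 64
    kernel: int = 3
    lstm_units: int = 64
    dense_units: tuple = (128, 64)
    expected_flatten: int | None = 14016  # None disables the check


@dataclass(frozen=True)
class LeNetSpec:
    input_shape: tuple = (64, 64, 1)
    conv1_filters: int = 6
    conv2_filters: int = 16
    kernel: int = 5
    dense_units: tuple = (120, 84)
    expected_flatten: int | None = 2704


def _check_flatten(model: Sequential, expected):
    if expected is None:
        return
    width = dict((r[0], r[1]) for r in model.layer_table())["flatten"][1]
    if width != expected:
        raise BuildError(
            f"flatten: width {width} does not match expected {expected} "
            "(input shape inconsistent with the architecture)"
        )


def build_cnn_lstm(spec: CNNLSTMSpec = CNNLSTMSpec(), seed: int = 0) -> Sequential:
    """Conv(3×3)→pool→Conv(3×3)→pool→flatten→reshape→LSTM→dense stack.

    The flattened conv output is reshaped to a length-14,016 sequence of
    1-dim steps for the LSTM, exactly as the architecture table prescribes.
    """
    h, w, c = spec.input_shape
    k = spec.kernel
    flat = ((h - k + 1) // 2 - k + 1) // 2 * (((w - k + 1) // 2 - k + 1) // 2) \
        * spec.conv2_filters
    model = Sequential(
        spec.input_shape,
        [
            Conv2D(spec.conv1_filters, k, name="conv1"),
            MaxPool2D(name="pool1"),
            Conv2D(spec.conv2_filters, k, name="conv2"),
            MaxPool2D(name="pool2"),
            Flatten(name="flatten"),
            Reshape((flat, 1), name="reshape"),
            LSTM(spec.lstm_units, name="lstm"),
            Dense(spec.dense_units[0], "relu", name="dense_128"),
            Dense(spec.dense_units[1], "relu", name="dense_64"),
            Dense(1, None, name="head"),
        ],
        seed=seed,
    )
    _check_flatten(model, spec.expected_flatten)
    return model


def build_lenet5(spec: LeNetSpec = LeNetSpec(), seed: int = 0) -> Sequential:
    """Classic LeNet-5 trunk with 120/84 dense layers and a sigmoid head."""
    model = Sequential(
        spec.input_shape,
        [
            Conv2D(spec.conv1_filters, spec.kernel, name="conv1"),
            MaxPool2D(name="pool1"),
            Conv2D(spec.conv2_filters, spec.kernel, name="conv2"),
            MaxPool2D(name="pool2"),
            Flatten(name="flatten"),
            Dense(spec.dense_units[0], "relu", name="dense_120"),
            Dense(spec.dense_units[1], "relu", name="dense_84"),
            Dense(1, None, name="head"),
        ],
        seed=seed,
    )
    _check_flatten(model, spec.expected_flatten)
    return model


def prepare_eeg_input(windows) -> np.ndarray:
    """Stack EEG windows to (B, 19, 300, 1), z-scored per window.

    Per-window standardisation keeps the network's input scale independent of
    the microvolt range left after cleaning.
    """
    X = np.stack([np.asarray(w, dtype=np.float32) for w in windows])
    mu = X.mean(axis=(1, 2), keepdims=True)
    sd = X.std(axis=(1, 2), keepdims=True)
    sd[sd == 0] = 1.0
    return ((X - mu) / sd)[..., None]


def prepare_gaze_input(plots) -> np.ndarray:
    """Stack 64×64 gaze plots to (B, 64, 64, 1) scaled to [0, 1]."""
    X = np.stack([np.asarray(p, dtype=np.float32) for p in plots])
    return (X / 255.0)[..., None]


def train_extractor(model: Sequential, X, y, cfg: TrainingConfig = TrainingConfig(),
                    max_samples: int | None = None):
    """Fit the extractor on (prepared) inputs; returns per-epoch mean loss.

    ``max_samples`` optionally subsamples the training set (stratified by
    taking a seeded permutation) — used by the pipeline to bound training
    cost on large window sets.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y).ravel()
    if max_samples is not None and len(X) > max_samples:
        rng = np.random.default_rng(cfg.seed)
        idx = rng.permutation(len(X))[:max_samples]
        if len(np.unique(y[idx])) < 2:  # keep both classes in the subsample
            pos = np.flatnonzero(y == 1)[:1]
            neg = np.flatnonzero(y == 0)[:1]
            idx = np.concatenate([idx[:-2], pos, neg])
        X, y = X[idx], y[idx]
    return model.fit(X, y, cfg)


def extract_features(model: Sequential, X, layer: str = "flatten") -> np.ndarray:
    """Activations of ``layer`` ∈ {"flatten", "last_dense"} for each input."""
    if layer == "flatten":
        name = "flatten"
    elif layer == "last_dense":
        dense = [l.name for l in model.layers if l.name.startswith("dense_")]
        if not dense:
            raise KeyError("model has no dense feature layer")
        name = dense[-1]
    else:
        raise KeyError(f"unknown extraction layer {layer!r}")
    return model.forward(np.asarray(X, dtype=np.float32), upto=name).astype(float)
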