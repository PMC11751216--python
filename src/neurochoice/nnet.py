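"""A small, deterministic NumPy neural-network engine.

Implements exactly the layer zoo the two feature extractors need — valid
stride-1 2-D convolution, 2×2 floor-mode max pooling, flatten/reshape, a
single-output LSTM, dense layers — with reverse-mode gradients, the Adam
update rule

    m_t = β₁ m_{t−1} + (1−β₁) g_t
    v_t = β₂ v_{t−1} + (1−β₂) g_t²
    θ_t = θ_{t−1} − η · m̂_t / (√v̂_t + ε)      (bias-corrected m̂, v̂)

and MSE / binary cross-entropy losses against a sigmoid head. Everything is
float32 and seeded, so training is bit-reproducible on a fixed BLAS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["TrainingConfig", "Sequential", "Conv2D", "MaxPool2D", "Flatten",
           "Reshape", "LSTM", "Dense", "BuildError"]

F32 = np.float32


class BuildError(ValueError):
    """Layer/shape inconsistency discovered while constructing a network."""


@dataclass(frozen=True)
class TrainingConfig:
    loss: str = "mse"          # "mse" | "bce", both against a sigmoid output
    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.beta1 < 1 and 0 < self.beta2 < 1):
            raise ValueError("Adam decay rates must lie in (0, 1)")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.loss not in ("mse", "bce"):
            raise ValueError(f"unknown loss {self.loss!r}")


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value):
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)


def _glorot(rng, shape, fan_in, fan_out):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape).astype(F32)


def _sigmoid(z):
    out = np.empty_like(z)
    np.negative(z, out=out)
    np.exp(out, out=out)
    out += 1.0
    np.reciprocal(out, out=out)
    return out


class Layer:
    name = "layer"

    def build(self, in_shape, rng):  # -> out_shape (without batch dim)
        raise NotImplementedError

    def params(self):
        return []

    def forward(self, x, train=False):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError


class Conv2D(Layer):
    """Valid-padding stride-1 convolution over (B, H, W, C) inputs, with an
    optional elementwise ReLU fused in."""

    def __init__(self, filters, ksize, relu=True, name="conv"):
        self.filters = filters
        self.ksize = ksize
        self.relu = relu
        self.name = name

    def build(self, in_shape, rng):
        if len(in_shape) != 3:
            raise BuildError(f"{self.name}: expected (H, W, C) input, got {in_shape}")
        h, w, c = in_shape
        k = self.ksize
        if h < k or w < k:
            raise BuildError(
                f"{self.name}: {k}×{k} kernel does not fit input {h}×{w}"
            )
        self.in_shape = in_shape
        fan_in = k * k * c
        self.W = Param(_glorot(rng, (fan_in, self.filters), fan_in, self.filters))
        self.b = Param(np.zeros(self.filters, dtype=F32))
        self.out_shape = (h - k + 1, w - k + 1, self.filters)
        return self.out_shape

    def params(self):
        return [self.W, self.b]

    @property
    def n_params(self):
        return self.W.value.size + self.b.value.size

    def _cols(self, x):
        k = self.ksize
        # (B, OH, OW, C, k, k) -> (B, OH, OW, k, k, C)
        v = sliding_window_view(x, (k, k), axis=(1, 2))
        v = np.ascontiguousarray(v.transpose(0, 1, 2, 4, 5, 3))
        b, oh, ow = v.shape[:3]
        return v.reshape(b * oh * ow, k * k * x.shape[3])

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=F32)
        b = x.shape[0]
        oh, ow, f = self.out_shape
        cols = self._cols(x)
        y = (cols @ self.W.value + self.b.value).reshape(b, oh, ow, f)
        if train:
            self._cols_cache = cols
            self._in_shape_b = x.shape
        if self.relu:
            if train:
                self._mask = y > 0
            np.maximum(y, 0, out=y)
        return y

    def backward(self, dy):
        if self.relu:
            dy = dy * self._mask
        b, oh, ow, f = dy.shape
        dflat = dy.reshape(-1, f)
        self.W.grad += self._cols_cache.T @ dflat
        self.b.grad += dflat.sum(axis=0)
        dcols = dflat @ self.W.value.T
        k = self.ksize
        _, h, w, c = self._in_shape_b
        dcols = dcols.reshape(b, oh, ow, k, k, c)
        dx = np.zeros(self._in_shape_b, dtype=F32)
        for i in range(k):
            for j in range(k):
                dx[:, i:i + oh, j:j + ow, :] += dcols[:, :, :, i, j, :]
        self._cols_cache = None
        return dx


class MaxPool2D(Layer):
    """2×2 max pooling, stride 2, floor mode (odd trailing rows/cols dropped)."""

    def __init__(self, name="pool"):
        self.name = name

    def build(self, in_shape, rng):
        h, w, c = in_shape
        self.in_shape = in_shape
        self.out_shape = (h // 2, w // 2, c)
        return self.out_shape

    def forward(self, x, train=False):
        b = x.shape[0]
        oh, ow, c = self.out_shape
        x_c = x[:, : oh * 2, : ow * 2, :]
        v = x_c.reshape(b, oh, 2, ow, 2, c)
        y = v.max(axis=(2, 4))
        if train:
            self._x_shape = x.shape
            self._mask = v == y[:, :, None, :, None, :]
        return y

    def backward(self, dy):
        b = dy.shape[0]
        oh, ow, c = self.out_shape
        dv = self._mask * dy[:, :, None, :, None, :]
        dx = np.zeros(self._x_shape, dtype=F32)
        dx[:, : oh * 2, : ow * 2, :] = dv.reshape(b, oh * 2, ow * 2, c)
        return dx


class Flatten(Layer):
    def __init__(self, name="flatten"):
        self.name = name

    def build(self, in_shape, rng):
        self.in_shape = in_shape
        self.out_shape = (int(np.prod(in_shape)),)
        return self.out_shape

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, target, name="reshape"):
        self.target = tuple(target)
        self.name = name

    def build(self, in_shape, rng):
        if int(np.prod(in_shape)) != int(np.prod(self.target)):
            raise BuildError(
                f"{self.name}: cannot reshape {in_shape} to {self.target}"
            )
        self.out_shape = self.target
        return self.out_shape

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, dy):
        return dy.reshape(self._shape)


class LSTM(Layer):
    """Single LSTM returning the last hidden state, over (B, T, D) input.

    Gate order in the packed weight matrices is [input, forget, output, cell].
    Parameter count is the standard 4·H·(D + H + 1).
    """

    def __init__(self, units, name="lstm"):
        self.units = units
        self.name = name

    def build(self, in_shape, rng):
        if len(in_shape) != 2:
            raise BuildError(f"{self.name}: expected (T, D) input, got {in_shape}")
        t, d = in_shape
        h = self.units
        self.T, self.D = t, d
        self.Wx = Param(_glorot(rng, (d, 4 * h), d + h, h))
        self.Wh = Param(_glorot(rng, (h, 4 * h), d + h, h))
        b = np.zeros(4 * h, dtype=F32)
        b[h:2 * h] = 1.0  # forget-gate bias, standard initialisation
        self.b = Param(b)
        self.out_shape = (h,)
        return self.out_shape

    def params(self):
        return [self.Wx, self.Wh, self.b]

    @property
    def n_params(self):
        return 4 * self.units * (self.D + self.units + 1)

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=F32)
        B, T, D = x.shape
        H = self.units
        h = np.zeros((B, H), dtype=F32)
        c = np.zeros((B, H), dtype=F32)
        Wx, Wh, b = self.Wx.value, self.Wh.value, self.b.value
        if train:
            gates = np.empty((T, B, 4 * H), dtype=F32)
            cs = np.empty((T, B, H), dtype=F32)
            self._x = x
        for t in range(T):
            g = x[:, t] @ Wx + h @ Wh + b
            g[:, :3 * H] = _sigmoid(g[:, :3 * H])
            g[:, 3 * H:] = np.tanh(g[:, 3 * H:])
            i, f, o, u = (g[:, :H], g[:, H:2 * H], g[:, 2 * H:3 * H], g[:, 3 * H:])
            c = f * c + i * u
            h = o * np.tanh(c)
            if train:
                gates[t] = g
                cs[t] = c
        if train:
            self._gates, self._cs = gates, cs
        return h

    def backward(self, dh_last):
        x, gates, cs = self._x, self._gates, self._cs
        B, T, D = x.shape
        H = self.units
        Wx, Wh = self.Wx.value, self.Wh.value
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H, dtype=F32)
        dx = np.empty_like(x)
        dh = dh_last.astype(F32)
        dc = np.zeros((B, H), dtype=F32)
        for t in range(T - 1, -1, -1):
            g = gates[t]
            i, f, o, u = (g[:, :H], g[:, H:2 * H], g[:, 2 * H:3 * H], g[:, 3 * H:])
            c = cs[t]
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c ** 2)
            c_prev = cs[t - 1] if t > 0 else np.zeros_like(c)
            h_prev = (gates[t - 1][:, 2 * H:3 * H] * np.tanh(cs[t - 1])
                      if t > 0 else np.zeros((B, H), dtype=F32))
            di = dc * u
            df = dc * c_prev
            du = dc * i
            dg = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o),
                 du * (1 - u ** 2)], axis=1)
            dWx += x[:, t].T @ dg
            dWh += h_prev.T @ dg
            db += dg.sum(axis=0)
            dx[:, t] = dg @ Wx.T
            dh = dg @ Wh.T
            dc = dc * f
        self.Wx.grad += dWx
        self.Wh.grad += dWh
        self.b.grad += db
        self._x = self._gates = self._cs = None
        return dx


class Dense(Layer):
    def __init__(self, units, activation="relu", name="dense"):
        if activation not in ("relu", "sigmoid", None):
            raise BuildError(f"unknown activation {activation!r}")
        self.units = units
        self.activation = activation
        self.name = name

    def build(self, in_shape, rng):
        if len(in_shape) != 1:
            raise BuildError(f"{self.name}: expected flat input, got {in_shape}")
        d = in_shape[0]
        self.W = Param(_glorot(rng, (d, self.units), d, self.units))
        self.b = Param(np.zeros(self.units, dtype=F32))
        self.out_shape = (self.units,)
        return self.out_shape

    def params(self):
        return [self.W, self.b]

    @property
    def n_params(self):
        return self.W.value.size + self.b.value.size

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=F32)
        y = x @ self.W.value + self.b.value
        if train:
            self._x = x
        if self.activation == "relu":
            if train:
                self._mask = y > 0
            np.maximum(y, 0, out=y)
        elif self.activation == "sigmoid":
            y = _sigmoid(y)
            if train:
                self._y = y
        return y

    def backward(self, dy):
        if self.activation == "relu":
            dy = dy * self._mask
        elif self.activation == "sigmoid":
            dy = dy * self._y * (1 - self._y)
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.W.value.T
        self._x = None
        return dx


class Adam:
    """Exact first/second-moment update with bias correction."""

    def __init__(self, params, cfg: TrainingConfig):
        self.params = params
        self.cfg = cfg
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        cfg = self.cfg
        self.t += 1
        b1t = 1 - cfg.beta1 ** self.t
        b2t = 1 - cfg.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= cfg.beta1
            m += (1 - cfg.beta1) * g
            v *= cfg.beta2
            v += (1 - cfg.beta2) * g * g
            p.value -= cfg.learning_rate * (m / b1t) / (np.sqrt(v / b2t)
                                                        + cfg.epsilon)
            p.grad[:] = 0


class Sequential:
    """Minimal sequential model with named layers and a layer table."""

    def __init__(self, input_shape, layers, seed=0):
        self.input_shape = tuple(input_shape)
        self.layers = layers
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in layers:
            shape = layer.build(shape, rng)
        names = [l.name for l in layers]
        if len(set(names)) != len(names):
            raise BuildError("layer names must be unique")

    # -- introspection -----------------------------------------------------
    def layer_table(self):
        """[(layer name, output shape incl. None batch dim, n parameters)]."""
        rows = [("input", (None,) + self.input_shape, 0)]
        for l in self.layers:
            n = getattr(l, "n_params", 0)
            rows.append((l.name, (None,) + tuple(l.out_shape), int(n)))
        return rows

    def n_params(self):
        return sum(getattr(l, "n_params", 0) for l in self.layers)

    # -- inference ---------------------------------------------------------
    def forward(self, x, upto=None, train=False, batch_size=256):
        """Forward pass; with ``upto`` stop after the layer of that name."""
        x = np.asarray(x, dtype=F32)
        if train:
            return self._forward_chunk(x, upto, True)
        outs = [self._forward_chunk(x[i:i + batch_size], upto, False)
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)

    def _forward_chunk(self, x, upto, train):
        for layer in self.layers:
            x = layer.forward(x, train=train)
            if upto is not None and layer.name == upto:
                return x
        if upto is not None:
            raise KeyError(f"no layer named {upto!r}")
        return x

    def predict_proba(self, x, batch_size=256):
        """Sigmoid of the (linear) head output."""
        return _sigmoid(self.forward(x, batch_size=batch_size)).ravel()

    # -- training ----------------------------------------------------------
    def fit(self, x, y, cfg: TrainingConfig = TrainingConfig()):
        """Minibatch training of the sigmoid head; returns per-epoch mean loss."""
        x = np.asarray(x, dtype=F32)
        y = np.asarray(y, dtype=F32).ravel()
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        params = [p for l in self.layers for p in l.params()]
        opt = Adam(params, cfg)
        rng = np.random.default_rng(cfg.seed)
        history = []
        n = len(x)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for s in range(0, n, cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                xb, yb = x[idx], y[idx]
                z = self._forward_chunk(xb, None, True).ravel()
                p = _sigmoid(z)
                m = len(idx)
                if cfg.loss == "mse":
                    losses.append(float(((yb - p) ** 2).mean()) * m)
                    dz = 2.0 * (p - yb) / m * p * (1 - p)
                else:  # bce: gradient simplifies through the sigmoid
                    eps = 1e-7
                    pc = np.clip(p, eps, 1 - eps)
                    losses.append(float(
                        -(yb * np.log(pc) + (1 - yb) * np.log(1 - pc)).mean()) * m)
                    dz = (p - yb) / m
                grad = dz.reshape(-1, 1).astype(F32)
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                opt.step()
            history.append(sum(losses) / n)
        return history
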