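"""Minimal dense/convolutional/recurrent layers with manual gradients.

Self-contained numpy building blocks for the breathing classifier: valid
1-D convolution, max pooling, an LSTM returning its final hidden state,
inverted dropout, dense layers, class-weighted binary cross-entropy on
logits, and Adam.  Shapes follow the (batch, time, channels) convention.

Gradients are exact analytic expressions (checked against finite
differences in the test suite), so training is deterministic for a fixed
seed on fixed data.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    train_only = False

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv1D(Layer):
    """Valid (unpadded) 1-D convolution over (B, T, C_in) → (B, T−k+1, C_out)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator, name: str):
        self.kernel = kernel
        self.W = Param(_glorot(rng, (kernel, in_ch, out_ch), kernel * in_ch, kernel * out_ch), f"{name}.W")
        self.b = Param(np.zeros(out_ch), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        k = self.kernel
        t_out = x.shape[1] - k + 1
        if t_out < 1:
            raise ValueError(f"sequence length {x.shape[1]} shorter than kernel {k}")
        y = np.tile(self.b.value, (x.shape[0], t_out, 1))
        for j in range(k):
            y += x[:, j : j + t_out, :] @ self.W.value[j]
        return y

    def backward(self, dy):
        x, k = self._x, self.kernel
        t_out = dy.shape[1]
        dx = np.zeros_like(x)
        for j in range(k):
            xs = x[:, j : j + t_out, :]
            self.W.grad[j] += np.einsum("bti,bto->io", xs, dy)
            dx[:, j : j + t_out, :] += dy @ self.W.value[j].T
        self.b.grad += dy.sum(axis=(0, 1))
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time; trailing remainder is dropped."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, train):
        b, t, c = x.shape
        t_out = t // self.pool
        xr = x[:, : t_out * self.pool, :].reshape(b, t_out, self.pool, c)
        self._argmax = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dy):
        b, t, c = self._in_shape
        t_out = dy.shape[1]
        dxr = np.zeros((b, t_out, self.pool, c))
        np.put_along_axis(dxr, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(self._in_shape)
        dx[:, : t_out * self.pool, :] = dxr.reshape(b, t_out * self.pool, c)
        return dx


class LSTM(Layer):
    """Standard LSTM over (B, T, C); emits the final hidden state (B, units).

    Gate order in the packed weight matrices is input, forget, candidate,
    output; the forget-gate bias is initialized to 1 (helps gradient flow
    early in training).
    """

    def __init__(self, in_ch: int, units: int, rng: np.random.Generator, name: str):
        self.units = units
        self.W = Param(_glorot(rng, (in_ch, 4 * units), in_ch, units), f"{name}.W")
        self.U = Param(_glorot(rng, (units, 4 * units), units, units), f"{name}.U")
        b = np.zeros(4 * units)
        b[units : 2 * units] = 1.0
        self.b = Param(b, f"{name}.b")

    def params(self):
        return [self.W, self.U, self.b]

    @staticmethod
    def _sigmoid(z):
        return 0.5 * (1.0 + np.tanh(0.5 * z))

    def forward(self, x, train):
        b, t, _ = x.shape
        u = self.units
        h = np.zeros((b, u))
        c = np.zeros((b, u))
        self._x = x
        self._cache = []
        for step in range(t):
            z = x[:, step, :] @ self.W.value + h @ self.U.value + self.b.value
            i = self._sigmoid(z[:, :u])
            f = self._sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = self._sigmoid(z[:, 3 * u :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            self._cache.append((i, f, g, o, c_prev, h_prev, c))
        self._h_last = h
        return h

    def backward(self, dh_last):
        x, u = self._x, self.units
        b, t, _ = x.shape
        dx = np.zeros_like(x)
        dh_next = dh_last
        dc_next = np.zeros((b, u))
        for step in range(t - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, c = self._cache[step]
            tanh_c = np.tanh(c)
            dh = dh_next
            do = dh * tanh_c * o * (1.0 - o)
            dc = dc_next + dh * o * (1.0 - tanh_c**2)
            di = dc * g * i * (1.0 - i)
            df = dc * c_prev * f * (1.0 - f)
            dg = dc * i * (1.0 - g**2)
            dz = np.concatenate([di, df, dg, do], axis=1)
            self.W.grad += x[:, step, :].T @ dz
            self.U.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, step, :] = dz @ self.W.value.T
            dh_next = dz @ self.U.value.T
            dc_next = dc * f
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, name: str, relu: bool = False):
        self.relu = relu
        self.W = Param(_glorot(rng, (in_dim, out_dim), in_dim, out_dim), f"{name}.W")
        self.b = Param(np.zeros(out_dim), f"{name}.b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        y = x @ self.W.value + self.b.value
        if self.relu:
            self._pre = y
            y = np.maximum(y, 0.0)
        return y

    def backward(self, dy):
        if self.relu:
            dy = dy * (self._pre > 0.0)
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Sequential:
    """A feed-forward stack; the last layer must emit logits of shape (B, 1)."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def n_parameters(self) -> int:
        """Brute-force tally over instantiated weight tensors."""
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x[:, 0]  # logits

    def backward(self, dlogits: np.ndarray) -> None:
        dy = dlogits[:, None]
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        out = np.empty(len(x))
        for lo in range(0, len(x), batch_size):
            z = self.forward(x[lo : lo + batch_size], train=False)
            out[lo : lo + batch_size] = sigmoid(z)
        return out

    def get_weights(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for p in self.params():
            value = weights[p.name]
            if value.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.value = value.astype(float).copy()
            p.grad = np.zeros_like(p.value)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def bce_with_logits(
    logits: np.ndarray, y: np.ndarray, sample_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean (optionally sample-weighted) binary cross-entropy and dL/dlogits."""
    n = len(logits)
    w = np.ones(n) if sample_weights is None else sample_weights
    # stable: max(z,0) − z·y + log(1 + exp(−|z|))
    per = np.maximum(logits, 0.0) - logits * y + np.log1p(np.exp(-np.abs(logits)))
    loss = float(np.mean(w * per))
    dlogits = w * (sigmoid(logits) - y) / n
    return loss, dlogits


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1.0 - b2**self.t) / (1.0 - b1**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1.0 - b1) * p.grad
            v[...] = b2 * v + (1.0 - b2) * p.grad**2
            p.value -= lr_t * m / (np.sqrt(v) + self.eps)
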