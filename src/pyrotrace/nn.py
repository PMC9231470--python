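"""Minimal seeded neural-network engine for 1-D spectral regression.

Implements exactly the layer set the thermometer needs — 1-D convolution
(same padding), ReLU, stride-2 average pooling, global average pooling
and dense layers — with hand-derived backpropagation and an Adam
optimizer.  Everything is plain numpy, seeded, and deterministic on a
fixed platform; gradients are validated against central finite
differences in the test suite.

Shapes follow the (batch, channels, length) convention.
"""

from __future__ import annotations

import numpy as np

from pyrotrace.exceptions import TrainingError


class Layer:
    """Base layer: forward caches whatever backward needs."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient) pairs; empty for stateless layers."""
        return []


class Conv1d(Layer):
    """1-D convolution with 'same' zero padding (odd kernel)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise TrainingError("convolution kernel must be odd for same padding")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        scale = np.sqrt(2.0 / (c_in * kernel))  # He initialization
        self.w = rng.normal(0.0, scale, size=(c_out, c_in * kernel))
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # (n, c, length, kernel) view -> (n, length, c*kernel)
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        return cols.transpose(0, 2, 1, 3).reshape(n, length, c * self.kernel)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = self._im2col(x)
        out = self._cols @ self.w.T + self.b  # (n, length, c_out)
        return out.transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, length = self._x_shape
        g = grad.transpose(0, 2, 1)  # (n, length, c_out)
        self.dw = np.einsum("nlo,nlk->ok", g, self._cols)
        self.db = g.sum(axis=(0, 1))
        dcols = g @ self.w  # (n, length, c_in*kernel)
        dcols = dcols.reshape(n, length, c, self.kernel)
        pad = self.kernel // 2
        dxp = np.zeros((n, c, length + 2 * pad))
        for k in range(self.kernel):
            dxp[:, :, k : k + length] += dcols[:, :, :, k].transpose(0, 2, 1)
        return dxp[:, :, pad : pad + length]

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class AvgPool1d(Layer):
    """Non-overlapping window-2, stride-2 average pooling (truncating)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_len = x.shape[2]
        half = self._in_len // 2
        x = x[:, :, : 2 * half]
        return 0.5 * (x[:, :, 0::2] + x[:, :, 1::2])

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, half = grad.shape
        dx = np.zeros((n, c, self._in_len))
        dx[:, :, 0 : 2 * half : 2] = 0.5 * grad
        dx[:, :, 1 : 2 * half : 2] = 0.5 * grad
        return dx


class GlobalAvgPool(Layer):
    """(n, c, length) -> (n, c) mean over length."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, :, None], self._length, axis=2) / self._length


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class Network:
    """A plain layer stack trained with Adam on mean squared error."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [pg for layer in self.layers for pg in layer.params()]

    # serialization ------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise TrainingError("weight list does not match architecture")
        for (p, _), w in zip(own, weights):
            if p.shape != w.shape:
                raise TrainingError(f"weight shape mismatch {p.shape} vs {w.shape}")
            p[...] = w


def build_cnn1d(
    input_len: int,
    channels: tuple[int, ...] = (16, 32, 64),
    kernel: int = 9,
    dense: tuple[int, ...] = (32,),
    rng: np.random.Generator | None = None,
) -> Network:
    """Convolution blocks (conv → ReLU → stride-2 pool) → global average
    pool → dense head → scalar."""
    rng = rng or np.random.default_rng(0)
    layers: list[Layer] = []
    c_prev = 1
    for c in channels:
        layers += [Conv1d(c_prev, c, kernel, rng), ReLU(), AvgPool1d()]
        c_prev = c
    layers.append(GlobalAvgPool())
    n_prev = c_prev
    for n in dense:
        layers += [Dense(n_prev, n, rng), ReLU()]
        n_prev = n
    layers.append(Dense(n_prev, 1, rng))
    return Network(layers)


def build_fcann(
    input_len: int,
    hidden: tuple[int, ...] = (64, 32),
    rng: np.random.Generator | None = None,
) -> Network:
    """Fully connected head over the flattened spectrum."""
    rng = rng or np.random.default_rng(0)
    layers: list[Layer] = [Flatten()]
    n_prev = input_len
    for n in hidden:
        layers += [Dense(n_prev, n, rng), ReLU()]
        n_prev = n
    layers.append(Dense(n_prev, 1, rng))
    return Network(layers)


class Adam:
    def __init__(self, net: Network, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in net.params()]
        self.v = [np.zeros_like(p) for p, _ in net.params()]

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.net.params()):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_mse(
    net: Network,
    x: np.ndarray,
    y: np.ndarray,
    epochs: int,
    batch_size: int,
    lr: float,
    seed: int,
) -> list[float]:
    """Mini-batch MSE training with Adam; returns the per-epoch loss curve.

    Raises :class:`TrainingError` naming the epoch if the loss goes
    non-finite.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(net, lr=lr)
    n = x.shape[0]
    losses: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = x[idx], y[idx]
            pred = net.forward(xb)[:, 0]
            resid = pred - yb
            loss = float(np.mean(resid**2))
            total += loss * idx.size
            net.backward((2.0 * resid / idx.size)[:, None])
            opt.step()
        epoch_loss = total / n
        if not np.isfinite(epoch_loss):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        losses.append(epoch_loss)
    return losses
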