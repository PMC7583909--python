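"""Minimal numpy neural-network layers with backprop and Adam.

Just enough machinery for the twin-tower convolutional pair classifier:
3x3 stride-1 convolution (im2col), ReLU, spatial batch normalization,
inverted dropout, dense layers and a fused sigmoid/binary-cross-entropy
head. All state is float32; randomness flows through an explicit
``np.random.Generator`` so training is reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "BatchNorm", "Dropout", "Dense", "Flatten", "Adam",
           "sigmoid", "bce_loss_and_grad"]

F32 = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_loss_and_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits; returns (loss, dlogits)."""
    p = sigmoid(logits)
    eps = 1e-7
    loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    return loss, ((p - y) / len(y)).astype(F32)


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Conv2D(Layer):
    """3x3 (or kxk) valid convolution, stride 1, NHWC layout."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        fan_in = kernel * kernel * c_in
        self.W = (rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in)).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.kernel = kernel
        self.c_in = c_in

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.kernel
        n, h, w, _ = x.shape
        ho, wo = h - k + 1, w - k + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        # win: (n, ho, wo, c, k, k) -> (n*ho*wo, k*k*c)
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * ho * wo, k * k * self.c_in)
        self._cols = cols.astype(F32)
        self._xshape = x.shape
        out = self._cols @ self.W + self.b
        return out.reshape(n, ho, wo, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k = self.kernel
        n, h, w, c = self._xshape
        ho, wo = h - k + 1, w - k + 1
        dflat = dout.reshape(-1, dout.shape[-1]).astype(F32)
        self.dW = self._cols.T @ dflat
        self.db = dflat.sum(axis=0)
        dcols = (dflat @ self.W.T).reshape(n, ho, wo, k, k, c)
        dx = np.zeros((n, h, w, c), dtype=F32)
        for ki in range(k):
            for kj in range(k):
                dx[:, ki : ki + ho, kj : kj + wo, :] += dcols[:, :, :, ki, kj, :]
        return dx

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0)


class BatchNorm(Layer):
    """Per-channel batch normalization over all leading axes (NHWC or NC)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=F32)
        self.beta = np.zeros(c, dtype=F32)
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(F32)
        self._xhat = ((x - mean) / self._std).astype(F32)
        self._axes = axes
        self._m = x.size // x.shape[-1]
        return self.gamma * self._xhat + self.beta

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = self._axes
        self.dgamma = (dout * self._xhat).sum(axis=axes)
        self.dbeta = dout.sum(axis=axes)
        m = self._m
        dxhat = dout * self.gamma
        dx = (
            dxhat - dxhat.mean(axis=axes) - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) / self._std
        return dx.astype(F32)

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return (dout @ self.W.T).astype(F32)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
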