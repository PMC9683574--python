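"""Minimal dense/convolutional layer kernels with explicit backpropagation.

Implemented directly on numpy so that training is single-threaded,
bit-deterministic and dependency-light. Layers follow a tiny protocol:
``forward(x, train)`` caches what backward needs; ``backward(dy)`` returns
``dx`` and stores parameter gradients in ``layer.grads`` (same ordering as
``layer.params``).

Tensor layout is channels-first: (batch, channels, time).
"""

from __future__ import annotations

import numpy as np

BN_EPS = 1e-5
BN_MOMENTUM = 0.9


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []


class Conv1d(Layer):
    """Same-padded 1-D convolution via im2col; kernel length is clipped by
    the caller to the series length."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = c_in * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel))
        b = np.zeros(c_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        w, b = self.params
        batch, _, t = x.shape
        k = self.kernel
        pad_l, pad_r = k // 2, (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad_l, pad_r)))
        # cols[b, t, ci, j] = xp[b, ci, t + j]
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        cols = cols.transpose(0, 2, 1, 3)  # (B, T, c_in, k)
        self._cols = cols.reshape(batch * t, self.c_in * k)
        self._x_shape = x.shape
        y = self._cols @ w.reshape(self.c_out, -1).T + b
        return y.reshape(batch, t, self.c_out).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        batch, _, t = self._x_shape
        k = self.kernel
        dyf = dy.transpose(0, 2, 1).reshape(batch * t, self.c_out)
        self.grads[0][...] = (dyf.T @ self._cols).reshape(w.shape)
        self.grads[1][...] = dyf.sum(axis=0)
        dcols = (dyf @ w.reshape(self.c_out, -1)).reshape(batch, t, self.c_in, k)
        pad_l, pad_r = k // 2, (k - 1) // 2
        dxp = np.zeros((batch, self.c_in, t + pad_l + pad_r))
        for j in range(k):
            dxp[:, :, j : j + t] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, pad_l : pad_l + t]


class BatchNorm1d(Layer):
    """Per-channel normalization over (batch, time); running stats at eval."""

    def __init__(self, channels: int):
        super().__init__()
        gamma = np.ones(channels)
        beta = np.zeros(channels)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        gamma, beta = self.params
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = BN_MOMENTUM * self.running_mean + (1 - BN_MOMENTUM) * mean
            self.running_var = BN_MOMENTUM * self.running_var + (1 - BN_MOMENTUM) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + BN_EPS)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return gamma[None, :, None] * xhat + beta[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        gamma, _ = self.params
        xhat, inv_std, train, shape = self._cache
        m = shape[0] * shape[2]
        self.grads[0][...] = (dy * xhat).sum(axis=(0, 2))
        self.grads[1][...] = dy.sum(axis=(0, 2))
        if not train:
            return dy * (gamma * inv_std)[None, :, None]
        dyxhat_sum = (dy * xhat).sum(axis=(0, 2)).reshape(1, -1, 1)
        dy_sum = dy.sum(axis=(0, 2)).reshape(1, -1, 1)
        g = (gamma * inv_std).reshape(1, -1, 1)
        return (g / m) * (m * dy - dy_sum - xhat * dyxhat_sum)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class GlobalAveragePool(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None], self._t, axis=2) / self._t


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        b = np.zeros(n_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ w.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(labels)), labels], 1e-12, None)
    return float(-np.log(p).mean())


class Adam:
    """Adaptive-moment mini-batch gradient descent at a fixed learning rate."""

    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class SGD:
    """Plain mini-batch gradient descent at a fixed learning rate."""

    def __init__(self, params, grads, lr=1e-3):
        self.params, self.grads, self.lr = params, grads, lr

    def step(self):
        for p, g in zip(self.params, self.grads):
            p -= self.lr * g
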