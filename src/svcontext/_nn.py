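"""Minimal NumPy neural-network engine for 1-D sequence models.

Implements exactly the layers the residual sequence CNN needs — 1-D
convolution (im2col + BLAS matmul), batch normalisation, ReLU, linear —
together with reverse-mode gradients, an AdamW optimiser with decoupled
weight decay, and a binary cross-entropy-with-logits loss.  Everything is
float32 and driven by an explicit ``numpy.random.Generator`` so runs are
reproducible bit-for-bit on a fixed seed and thread count.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv1d",
    "BatchNorm1d",
    "Linear",
    "AdamW",
    "bce_with_logits",
    "sigmoid",
]

_F32 = np.float32


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy on raw logits.

    Returns ``(loss, dlogits)`` where ``dlogits`` is the gradient of the
    mean loss.  Uses the softplus identity ``BCE = softplus(z) - y*z`` which
    is stable for large |z|.
    """
    z = logits.astype(np.float64).ravel()
    y = targets.astype(np.float64).ravel()
    softplus = np.where(z > 30, z, np.log1p(np.exp(np.minimum(z, 30.0))))
    loss = float(np.mean(softplus - y * z))
    dz = (sigmoid(z) - y) / z.size
    return loss, dz.reshape(logits.shape).astype(_F32)


class Layer:
    """Base class: parameters are (name, value, grad) triples."""

    def params(self):
        return []

    def forward(self, x, train=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv1d(Layer):
    """1-D cross-correlation with 'same' padding semantics.

    Input/output layout is ``(N, C, L)``.  The forward pass lowers the
    input to a ``(N*L, C*K)`` matrix so the contraction runs through BLAS.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int, rng: np.random.Generator):
        fan_in = in_channels * kernel_size
        bound = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU nets
        self.W = rng.normal(0.0, bound, (out_channels, in_channels, kernel_size)).astype(_F32)
        self.b = np.zeros(out_channels, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel_size = kernel_size
        self.padding = padding
        self._col = None
        self._in_shape = None

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x, train=False):
        N, C, L = x.shape
        K, P = self.kernel_size, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (P, P))) if P else x
        Lout = L + 2 * P - K + 1
        col = sliding_window_view(xp, K, axis=2)          # (N, C, Lout, K)
        col = np.ascontiguousarray(col.transpose(0, 2, 1, 3)).reshape(N, Lout, C * K)
        Cout = self.W.shape[0]
        y = col @ self.W.reshape(Cout, C * K).T + self.b
        if train:
            self._col = col
            self._in_shape = (N, C, L)
        return y.transpose(0, 2, 1)                        # (N, Cout, Lout)

    def backward(self, dout):
        N, C, L = self._in_shape
        K, P = self.kernel_size, self.padding
        Cout = self.W.shape[0]
        d = dout.transpose(0, 2, 1)                        # (N, Lout, Cout)
        Lout = d.shape[1]
        dmat = d.reshape(N * Lout, Cout)
        colmat = self._col.reshape(N * Lout, C * K)
        self.dW[...] = (dmat.T @ colmat).reshape(self.W.shape)
        self.db[...] = dmat.sum(axis=0)
        dcol = (dmat @ self.W.reshape(Cout, C * K)).reshape(N, Lout, C, K)
        dxp = np.zeros((N, C, L + 2 * P), dtype=_F32)
        # scatter-add the K taps back onto the padded input
        for k in range(K):
            dxp[:, :, k:k + Lout] += dcol[:, :, :, k].transpose(0, 2, 1)
        self._col = None
        return dxp[:, :, P:P + L] if P else dxp


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over (N, L) for (N, C, L) input."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(channels, dtype=_F32)
        self.beta = np.zeros(channels, dtype=_F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.eps = eps
        self.momentum = momentum
        self._cache = None

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2), dtype=np.float64)
            var = x.var(axis=(0, 2), dtype=np.float64)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(_F32)
        xhat = (x - mean.astype(_F32)[None, :, None]) * inv[None, :, None]
        if train:
            self._cache = (xhat, inv, x.shape[0] * x.shape[2])
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dout):
        xhat, inv, m = self._cache
        self.dgamma[...] = (dout * xhat).sum(axis=(0, 2))
        self.dbeta[...] = dout.sum(axis=(0, 2))
        dxhat = dout * self.gamma[None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        dx = (dxhat - s1 / m - xhat * s2 / m) * inv[None, :, None]
        self._cache = None
        return dx.astype(_F32)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        bound = np.sqrt(2.0 / in_features)
        self.W = rng.normal(0.0, bound, (out_features, in_features)).astype(_F32)
        self.b = np.zeros(out_features, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW[...] = dout.T @ self._x
        self.db[...] = dout.sum(axis=0)
        dx = dout @ self.W
        self._x = None
        return dx


class AdamW:
    """Adam with decoupled weight decay (weight decay skips biases/BN)."""

    def __init__(self, layers, lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.slots = []
        for layer in layers:
            for name, value, grad in layer.params():
                decay = name == "W"
                self.slots.append((value, grad, np.zeros_like(value),
                                   np.zeros_like(value), decay))

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for value, grad, m, v, decay in self.slots:
            m *= self.b1
            m += (1 - self.b1) * grad
            v *= self.b2
            v += (1 - self.b2) * grad * grad
            if decay and self.weight_decay:
                value *= 1.0 - self.lr * self.weight_decay
            value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
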