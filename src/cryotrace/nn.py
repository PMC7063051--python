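"""Minimal 3D convolutional network primitives in numpy.

Implements exactly what the cascaded segmentation model needs: stride-1
"same"-padded 3D convolution (cross-correlation convention) with optional
dilation, leaky ReLU, softmax cross-entropy with per-class weights, and Adam.
Convolution is evaluated as one GEMM per kernel tap over shifted views of the
zero-padded input, which keeps all heavy lifting in BLAS; the same loop
structure yields the input and weight gradients in the backward pass.

Layers operate on single volumes shaped ``(channels, D, H, W)`` (batch size
one: the training unit is one cube).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

DTYPE = np.float32


class Conv3d:
    """Stride-1 same-padded 3D convolution with dilation.

    ``y[o, p] = b[o] + sum_{i, a} w[o, i, a] * x[i, p + a*dilation - pad_low]``
    with zero padding; output spatial shape equals input spatial shape.
    For even effective kernel extents the extra padding voxel goes on the
    high side.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        dilation: int = 1,
        rng: Optional[np.random.Generator] = None,
        dtype=DTYPE,
    ):
        self.cin = in_channels
        self.cout = out_channels
        self.k = kernel
        self.dilation = dilation
        self.extent = (kernel - 1) * dilation + 1
        self.pad_low = (self.extent - 1) // 2
        self.dtype = dtype
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel**3
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(out_channels, in_channels, kernel, kernel, kernel)
                            ).astype(dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._xp: Optional[np.ndarray] = None
        self._shape: Optional[tuple] = None

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def _taps(self):
        k, d = self.k, self.dilation
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    yield (a, b, c), (a * d, b * d, c * d)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cin, D, H, W = x.shape
        if cin != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {cin}")
        e, pl = self.extent, self.pad_low
        xp = np.zeros((cin, D + e - 1, H + e - 1, W + e - 1), dtype=self.dtype)
        xp[:, pl : pl + D, pl : pl + H, pl : pl + W] = x
        V = D * H * W
        y = np.zeros((self.cout, V), dtype=self.dtype)
        tmp = np.empty_like(y)
        xs = np.empty((cin, V), dtype=self.dtype)
        for (a, b, c), (sa, sb, sc) in self._taps():
            xs[...] = xp[:, sa : sa + D, sb : sb + H, sc : sc + W].reshape(cin, V)
            np.matmul(self.w[:, :, a, b, c], xs, out=tmp)
            y += tmp
        y += self.b[:, None]
        self._xp, self._shape = xp, (D, H, W)
        return y.reshape(self.cout, D, H, W)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self._xp is None:
            raise RuntimeError("backward before forward")
        D, H, W = self._shape
        V = D * H * W
        gy_flat = np.ascontiguousarray(gy.reshape(self.cout, V), dtype=self.dtype)
        e, pl = self.extent, self.pad_low
        gxp = np.zeros_like(self._xp)
        xs = np.empty((self.cin, V), dtype=self.dtype)
        for (a, b, c), (sa, sb, sc) in self._taps():
            xs[...] = self._xp[:, sa : sa + D, sb : sb + H, sc : sc + W].reshape(
                self.cin, V)
            self.gw[:, :, a, b, c] += gy_flat @ xs.T
            gxp[:, sa : sa + D, sb : sb + H, sc : sc + W] += (
                self.w[:, :, a, b, c].T @ gy_flat
            ).reshape(self.cin, D, H, W)
        self.gb += gy_flat.sum(axis=1)
        gx = gxp[:, pl : pl + D, pl : pl + H, pl : pl + W]
        self._xp = None
        return gx


class LeakyReLU:
    """max(x, alpha*x); the paper's activation with alpha = 0.1."""

    def __init__(self, alpha: float = 0.1):
        self.alpha = alpha
        self._mask: Optional[np.ndarray] = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, self.alpha * gy)


class Sequential:
    def __init__(self, layers: Sequence):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


def softmax(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(p: np.ndarray, gp: np.ndarray, axis: int = 0) -> np.ndarray:
    """Vector-Jacobian product of softmax: returns gradient w.r.t. logits."""
    dot = (gp * p).sum(axis=axis, keepdims=True)
    return p * (gp - dot)


def weighted_cross_entropy(
    p: np.ndarray, target: np.ndarray, class_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean per-voxel weighted cross-entropy and its gradient w.r.t. logits.

    ``p`` are softmax probabilities (C, ...), ``target`` a one-hot array of
    the same shape. The gradient returned is d(loss)/d(logits), i.e. the
    usual ``weight * (p - t) / n`` with the weight of each voxel's true class.
    """
    eps = np.finfo(np.float64).tiny
    n_vox = p[0].size
    wvox = np.einsum("c...,c->...", target.astype(np.float64),
                     class_weights.astype(np.float64))
    loss = -(wvox * np.log(np.einsum("c...,c...->...", target, p) + eps)).sum() / n_vox
    glogits = (p - target) * wvox[None] / n_vox
    return float(loss), glogits.astype(p.dtype)


def inverse_frequency_weights(targets: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-class weights proportional to 1/frequency, normalized to mean 1.

    ``targets`` is a one-hot stack (C, ...) aggregated over the dataset.
    """
    counts = targets.reshape(n_classes, -1).sum(axis=1).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    w = 1.0 / counts
    return (w / w.mean()).astype(np.float64)


class Adam:
    """Adaptive-moment optimizer over (param, grad) pairs."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]
        self.t = 0

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0

    def step(self):
        self.t += 1
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
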