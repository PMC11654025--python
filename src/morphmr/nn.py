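"""Minimal residual convolutional network in numpy.

A compact, CPU-oriented implementation of the few primitives the morphology
classifier needs: 3x3/1x1 convolutions (NHWC layout, im2col + matmul), ReLU,
residual blocks with projection shortcuts, global average pooling, a dense
head, sigmoid/binary cross-entropy with class weights, and Adam.  Gradients
are hand-derived and verified against finite differences in the test suite.

The network is a 10-weight-layer residual design: one stem convolution,
four residual blocks of two 3x3 convolutions each (the first three blocks
downsample by stride 2), global average pooling, then a single dense sigmoid
unit that also receives the standardised lesion diameter as an extra scalar
feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _he_init(rng: np.random.Generator, fan_in: int, shape: Tuple[int, ...]) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv2D:
    """kxk convolution, NHWC, zero padding to keep H/W divisible by stride."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k - 1) // 2
        self.W = _he_init(rng, c_in * k * k, (c_in * k * k, c_out))
        self.b = np.zeros(c_out)
        self._cols: Optional[np.ndarray] = None
        self._x_shape: Optional[Tuple[int, ...]] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        assert c == self.c_in, f"expected {self.c_in} channels, got {c}"
        p, s, k = self.pad, self.stride, self.k
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # windows: (n, ho*s, wo*s, c, k, k) view, subsampled by stride
        win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::s, ::s]
        n_, ho, wo = win.shape[:3]
        cols = win.reshape(n_, ho, wo, c * k * k)
        out = cols @ self.W + self.b
        self._cols = cols
        self._x_shape = (n, h, w, c)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x_shape
        p, s, k = self.pad, self.stride, self.k
        ho, wo = dout.shape[1], dout.shape[2]
        cols2 = self._cols.reshape(-1, c * k * k)
        dflat = dout.reshape(-1, self.c_out)
        self.dW = cols2.T @ dflat
        self.db = dflat.sum(axis=0)
        dcols = (dout @ self.W.T).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c))
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + s * ho : s, j : j + s * wo : s, :] += dcols[..., i, j]
        return dxp[:, p : p + h, p : p + w, :] if p else dxp

    def params(self) -> List[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> List[np.ndarray]:
        return [self.dW, self.db]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class ResidualBlock:
    """conv-relu-conv with a projection shortcut when shape changes."""

    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2D(c_in, c_out, 3, stride, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(c_out, c_out, 3, 1, rng)
        self.project = c_in != c_out or stride != 1
        self.skip = Conv2D(c_in, c_out, 1, stride, rng) if self.project else None
        self.relu_out = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        main = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        shortcut = self.skip.forward(x) if self.project else x
        return self.relu_out.forward(main + shortcut)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu_out.backward(dout)
        dx_main = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        dx_skip = self.skip.backward(d) if self.project else d
        return dx_main + dx_skip

    def params(self) -> List[np.ndarray]:
        out = self.conv1.params() + self.conv2.params()
        if self.project:
            out += self.skip.params()
        return out

    def grads(self) -> List[np.ndarray]:
        out = self.conv1.grads() + self.conv2.grads()
        if self.project:
            out += self.skip.grads()
        return out


class ResNetSmall:
    """Residual network for 64x64 single-channel ROIs + a scalar size feature.

    ``forward`` returns logits; ``predict_proba`` applies the sigmoid.  The
    scalar feature (standardised lesion diameter) is concatenated to the
    pooled representation before the final dense unit.
    """

    INPUT_SIZE = 64

    def __init__(self, widths: Sequence[int] = (16, 32, 64, 128), seed: int = 0):
        if len(widths) != 4:
            raise ValueError("widths must list the four residual block widths")
        rng = np.random.default_rng(seed)
        w0, w1, w2, w3 = widths
        self.widths = tuple(widths)
        self.seed = seed
        self.stem = Conv2D(1, w0, 3, 2, rng)
        self.stem_relu = ReLU()
        self.blocks = [
            ResidualBlock(w0, w1, 2, rng),
            ResidualBlock(w1, w2, 2, rng),
            ResidualBlock(w2, w3, 2, rng),
            ResidualBlock(w3, w3, 1, rng),
        ]
        self.head_W = rng.standard_normal((w3 + 1, 1)) * np.sqrt(1.0 / (w3 + 1))
        self.head_b = np.zeros(1)

    # -- forward / backward -------------------------------------------------

    def forward(self, images: np.ndarray, diam_z: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim != 3 or images.shape[1:] != (self.INPUT_SIZE, self.INPUT_SIZE):
            raise ValueError(
                f"expected images of shape (n, {self.INPUT_SIZE}, {self.INPUT_SIZE}), "
                f"got {images.shape}"
            )
        diam_z = np.asarray(diam_z, dtype=np.float64).reshape(-1)
        if diam_z.shape[0] != images.shape[0]:
            raise ValueError("diameter feature length must match image count")
        x = images[..., None]
        x = self.stem_relu.forward(self.stem.forward(x))
        for blk in self.blocks:
            x = blk.forward(x)
        pooled = x.mean(axis=(1, 2))  # global average pool
        self._pool_shape = x.shape
        feats = np.concatenate([pooled, diam_z[:, None]], axis=1)
        self._feats = feats
        return (feats @ self.head_W + self.head_b).reshape(-1)

    def backward(self, dlogit: np.ndarray) -> None:
        dlogit = dlogit.reshape(-1, 1)
        self.d_head_W = self._feats.T @ dlogit
        self.d_head_b = dlogit.sum(axis=0)
        dfeats = dlogit @ self.head_W.T
        dpooled = dfeats[:, :-1]
        n, h, w, c = self._pool_shape
        dx = np.broadcast_to(dpooled[:, None, None, :], (n, h, w, c)) / (h * w)
        for blk in reversed(self.blocks):
            dx = blk.backward(dx)
        self.stem.backward(self.stem_relu.backward(dx))

    def predict_proba(self, images: np.ndarray, diam_z: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(images, diam_z))

    # -- parameter access ---------------------------------------------------

    def params(self) -> List[np.ndarray]:
        out = self.stem.params()
        for blk in self.blocks:
            out += blk.params()
        out += [self.head_W, self.head_b]
        return out

    def grads(self) -> List[np.ndarray]:
        out = self.stem.grads()
        for blk in self.blocks:
            out += blk.grads()
        out += [self.d_head_W, self.d_head_b]
        return out

    def get_weights(self) -> List[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(
    logits: np.ndarray, targets: np.ndarray, sample_weights: Optional[np.ndarray] = None
) -> Tuple[float, np.ndarray]:
    """Weighted binary cross-entropy on logits; returns (loss, dlogits)."""
    z, y = np.asarray(logits, float), np.asarray(targets, float)
    w = np.ones_like(z) if sample_weights is None else np.asarray(sample_weights, float)
    # softplus(z) - y*z, computed stably
    loss_terms = np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))
    wsum = w.sum()
    loss = float((w * loss_terms).sum() / wsum)
    dz = w * (sigmoid(z) - y) / wsum
    return loss, dz


class Adam:
    """Adam optimiser over a flat parameter list (in-place updates)."""

    def __init__(self, params: List[np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
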