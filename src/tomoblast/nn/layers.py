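"""Differentiable layers (forward + hand-derived backward) on NumPy arrays.

Activations are ``float32`` of shape ``(N, C, D, H, W)``.  Each layer caches
what its backward pass needs during ``forward`` and accumulates parameter
gradients into ``grads`` (zeroed by the optimizer step).  Convolutions use
im2col with a per-sample loop so peak memory stays modest on large grids.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Layer", "Conv3d", "InstanceNorm", "LeakyReLU", "MaxPool2",
           "Upsample2", "GlobalAvgPool", "Dense", "Adam"]


class Layer:
    """Base class: parameterless layers leave ``params`` empty."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self):
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


class Conv3d(Layer):
    """3D convolution, stride 1, 'same' zero padding, kernel 1 or 3."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 needs_input_grad: bool = True):
        super().__init__()
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.needs_input_grad = needs_input_grad
        fan_in = c_in * kernel ** 3
        # He initialization (leaky-ReLU pre-activations upstream)
        w = rng.standard_normal((c_out, c_in) + (kernel,) * 3) * math.sqrt(2.0 / fan_in)
        self.params = {"w": w.astype(np.float32),
                       "b": np.zeros(c_out, dtype=np.float32)}
        self.zero_grad()

    def _conv(self, x: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Correlate a batch with a (Co, Ci, k, k, k) kernel, same padding.

        k = 3 uses shifted-view accumulation (27 channel-mixing tensordots on
        views of the padded input), which avoids the large column-matrix copy
        of classic im2col and is memory-bandwidth friendly on a single CPU.
        """
        k = w.shape[-1]
        n, c, d, h, wd = x.shape
        co = w.shape[0]
        if k == 1:
            wm = w.reshape(co, c)
            y = wm @ x.reshape(n, c, -1)
            return y.reshape(n, co, d, h, wd)
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        acc = np.zeros((co, n, d, h, wd), dtype=np.float32)
        for dz in range(k):
            for dyy in range(k):
                for dx in range(k):
                    xs = xp[:, :, dz:dz + d, dyy:dyy + h, dx:dx + wd]
                    acc += np.tensordot(w[:, :, dz, dyy, dx], xs, axes=([1], [1]))
        return np.ascontiguousarray(np.moveaxis(acc, 0, 1))

    def forward(self, x, training=True):
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._x = x if training else None
        y = self._conv(x, self.params["w"])
        return y + self.params["b"][None, :, None, None, None]

    def backward(self, dy):
        x, w, k = self._x, self.params["w"], self.k
        n, c, d, h, wd = x.shape
        co = w.shape[0]
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        self.grads["b"] += dy.sum(axis=(0, 2, 3, 4))
        if k == 1:
            dyf = dy.reshape(n, co, -1)
            xf = x.reshape(n, c, -1)
            self.grads["w"] += np.einsum("nov,ncv->oc", dyf, xf, optimize=True) \
                .reshape(w.shape)
        else:
            # dW by offset-wise contraction over shifted views (no column copy)
            p = k // 2
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
            dw = np.empty_like(self.grads["w"])
            for dz in range(k):
                for dhh in range(k):
                    for dx in range(k):
                        xs = xp[:, :, dz:dz + d, dhh:dhh + h, dx:dx + wd]
                        dw[:, :, dz, dhh, dx] = np.tensordot(
                            dy, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
            self.grads["w"] += dw
        if not self.needs_input_grad:
            return None
        # dx: correlate dy with the spatially flipped, channel-swapped kernel
        w_t = np.ascontiguousarray(w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
        return self._conv(dy, w_t)


class InstanceNorm(Layer):
    """Per-sample, per-channel normalization over the spatial axes (affine)."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.params = {"gamma": np.ones(channels, dtype=np.float32),
                       "beta": np.zeros(channels, dtype=np.float32)}
        self.zero_grad()

    def forward(self, x, training=True):
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        var = x.var(axis=(2, 3, 4), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if training:
            self._xhat, self._inv = xhat, inv
        return self.params["gamma"][None, :, None, None, None] * xhat \
            + self.params["beta"][None, :, None, None, None]

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        g = self.params["gamma"][None, :, None, None, None]
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3, 4))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3, 4))
        dxhat = dy * g
        m1 = dxhat.mean(axis=(2, 3, 4), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3, 4), keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.1):
        super().__init__()
        self.slope = slope

    def forward(self, x, training=True):
        if training:
            self._neg = x < 0
        return np.where(x < 0, self.slope * x, x)

    def backward(self, dy):
        out = dy.copy()
        out[self._neg] *= self.slope
        return out


class MaxPool2(Layer):
    """2x2x2 max pooling (spatial dims must be even)."""

    def forward(self, x, training=True):
        n, c, d, h, w = x.shape
        blocks = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2) \
            .transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d // 2, h // 2, w // 2, 8)
        idx = blocks.argmax(axis=-1)
        if training:
            self._idx, self._shape = idx, x.shape
        return np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        n, c, d, h, w = self._shape
        out = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
        np.put_along_axis(out, self._idx[..., None], dy[..., None], axis=-1)
        return out.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2) \
            .transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)


class Upsample2(Layer):
    """2x nearest-neighbour resize along each spatial axis."""

    def forward(self, x, training=True):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dy):
        n, c, d, h, w = dy.shape
        return dy.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))


class GlobalAvgPool(Layer):
    def forward(self, x, training=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy):
        n, c, d, h, w = self._shape
        return np.broadcast_to(
            dy[:, :, None, None, None] / (d * h * w), self._shape
        ).astype(dy.dtype)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.standard_normal((n_out, n_in)) * math.sqrt(2.0 / n_in)
        self.params = {"w": w.astype(np.float32),
                       "b": np.zeros(n_out, dtype=np.float32)}
        self.zero_grad()

    def forward(self, x, training=True):
        if training:
            self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, dy):
        self.grads["w"] += dy.T @ self._x
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["w"]


class Adam:
    """Adam with decoupled weight decay (applied to weight tensors only).

    The learning-rate decay value configured for the training recipe is read
    as an AdamW-style decoupled decay; a multiplicative per-epoch decay can be
    emulated by adjusting the schedule instead.
    """

    def __init__(self, layers, lr: float = 5e-4, beta1: float = 0.5,
                 beta2: float = 0.999, weight_decay: float = 1e-4, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2 = lr, beta1, beta2
        self.weight_decay, self.eps = weight_decay, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m = self.m[li][k]
                v = self.v[li][k]
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                update = (m / b1c) / (np.sqrt(v / b2c) + self.eps)
                if k == "w" and self.weight_decay:
                    p -= lr * self.weight_decay * p
                p -= lr * update

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()
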