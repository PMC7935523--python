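"""A compact convolutional network for CPU training.

Convolutions are direct 3x3 stride-1 kernels JIT-compiled with numba (the
inner channel loop vectorizes); dense layers, pooling, and the optimizer
run on NumPy.  Everything is float32 and deterministic for a fixed seed.

Deliberately minimal: 3x3 same-padding convolutions, 2x2 max pooling,
dense layers, ReLU, softmax cross-entropy, and SGD with classical
momentum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["Conv3x3", "MaxPool2", "Dense", "SmallConvNet"]


@njit(fastmath=True)
def _conv_fw(xp, w, b, out):
    n_im, h, wd, c_out = out.shape
    c_in = xp.shape[3]
    acc = np.empty(c_out, dtype=np.float32)
    for n in range(n_im):
        for y in range(h):
            for x in range(wd):
                acc[:] = b
                for dy in range(3):
                    for dx in range(3):
                        for ci in range(c_in):
                            v = xp[n, y + dy, x + dx, ci]
                            for co in range(c_out):
                                acc[co] += v * w[dy, dx, ci, co]
                out[n, y, x, :] = acc


@njit(fastmath=True)
def _conv_dw(xp, dout, dw, db):
    n_im, h, wd, c_out = dout.shape
    c_in = xp.shape[3]
    for n in range(n_im):
        for y in range(h):
            for x in range(wd):
                for co in range(c_out):
                    db[co] += dout[n, y, x, co]
                for dy in range(3):
                    for dx in range(3):
                        for ci in range(c_in):
                            v = xp[n, y + dy, x + dx, ci]
                            for co in range(c_out):
                                dw[dy, dx, ci, co] += v * dout[n, y, x, co]


@njit(fastmath=True)
def _conv_dx(dout, w, dxp):
    n_im, h, wd, c_out = dout.shape
    c_in = dxp.shape[3]
    for n in range(n_im):
        for y in range(h):
            for x in range(wd):
                for dy in range(3):
                    for dx in range(3):
                        for ci in range(c_in):
                            s = np.float32(0.0)
                            for co in range(c_out):
                                s += dout[n, y, x, co] * w[dy, dx, ci, co]
                            dxp[n, y + dy, x + dx, ci] += s


def _pad1(x: np.ndarray) -> np.ndarray:
    return np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))


class Conv3x3:
    """3x3 same-padding convolution, NHWC, stride 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = math.sqrt(2.0 / (9 * c_in))
        self.w = (std * rng.standard_normal((3, 3, c_in, c_out))).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, _ = x.shape
        xp = _pad1(x)
        out = np.empty((n, h, w, self.b.shape[0]), dtype=np.float32)
        _conv_fw(xp, self.w, self.b, out)
        self._xp = xp if train else None
        return out

    def backward(self, dout: np.ndarray, *, need_dx: bool = True):
        dw = np.zeros_like(self.w)
        db = np.zeros_like(self.b)
        _conv_dw(self._xp, dout, dw, db)
        dx = None
        if need_dx:
            dxp = np.zeros_like(self._xp)
            _conv_dx(dout, self.w, dxp)
            dx = dxp[:, 1:-1, 1:-1, :]
        self._xp = None
        return dx, [dw, db]

    @property
    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]


class MaxPool2:
    """2x2 max pooling, stride 2, NHWC."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        if train:
            # distribute gradient equally over tied maxima
            mask = xr == out[:, :, None, :, None, :]
            self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
            self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray):
        n, h, w, c = self._shape
        dx = (self._mask * dout[:, :, None, :, None, :]).reshape(n, h, w, c)
        dx = np.ascontiguousarray(dx, dtype=np.float32)
        self._mask = None
        return dx, []

    params: list[np.ndarray] = []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = math.sqrt(2.0 / n_in)
        self.w = (std * rng.standard_normal((n_in, n_out))).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray):
        dw = self._x.T @ dout
        db = dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx, [dw, db]

    @property
    def params(self) -> list[np.ndarray]:
        return [self.w, self.b]


@dataclass
class SGDMomentum:
    lr: float = 0.01
    momentum: float = 0.9
    velocity: list[np.ndarray] = field(default_factory=list)

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self.velocity:
            self.velocity = [np.zeros_like(p) for p in params]
        for p, g, v in zip(params, grads, self.velocity):
            v *= self.momentum
            v -= self.lr * g
            p += v


class SmallConvNet:
    """conv16-pool-conv32-pool-conv64-pool-dense128-dense(n_classes).

    Input is NHWC float32; spatial size must be divisible by 8.
    """

    def __init__(
        self,
        input_size: int,
        n_classes: int,
        seed: int,
        *,
        widths: tuple[int, int, int] = (16, 32, 64),
        hidden: int = 128,
        lr: float = 0.01,
        momentum: float = 0.9,
    ):
        rng = np.random.default_rng(seed)
        w1, w2, w3 = widths
        self.convs = [
            Conv3x3(3, w1, rng),
            Conv3x3(w1, w2, rng),
            Conv3x3(w2, w3, rng),
        ]
        self.pools = [MaxPool2(), MaxPool2(), MaxPool2()]
        feat = (input_size // 8) ** 2 * w3
        self.fc1 = Dense(feat, hidden, rng)
        self.fc2 = Dense(hidden, n_classes, rng)
        self.opt = SGDMomentum(lr=lr, momentum=momentum)

    def _forward(self, x: np.ndarray, train: bool):
        acts = []
        h = x
        for conv, pool in zip(self.convs, self.pools):
            h = conv.forward(h, train)
            mask = h > 0
            h = h * mask
            if train:
                acts.append(mask)
            h = pool.forward(h, train)
        n = h.shape[0]
        flat = h.reshape(n, -1)
        z = self.fc1.forward(flat, train)
        mask_fc = z > 0
        z = z * mask_fc
        if train:
            acts.append(mask_fc)
            self._relu_masks = acts
            self._pool_out_shape = h.shape
        return self.fc2.forward(z, train)

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self._forward(x, train=False)

    def train_batch(self, x: np.ndarray, y: np.ndarray) -> float:
        """One SGD step on a batch; returns the mean cross-entropy loss."""
        n = x.shape[0]
        logits = self._forward(x, train=True)
        logits = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        probs = expz / expz.sum(axis=1, keepdims=True)
        loss = float(-np.log(probs[np.arange(n), y] + 1e-12).mean())
        d = probs
        d[np.arange(n), y] -= 1.0
        d /= np.float32(n)

        grads_rev: list[np.ndarray] = []
        d, g = self.fc2.backward(d)
        grads_rev.extend(reversed(g))
        d = d * self._relu_masks[3]
        d, g = self.fc1.backward(d)
        grads_rev.extend(reversed(g))
        d = np.ascontiguousarray(d.reshape(self._pool_out_shape), dtype=np.float32)
        for i in (2, 1, 0):
            d, _ = self.pools[i].backward(d)
            d = d * self._relu_masks[i]
            d = np.ascontiguousarray(d, dtype=np.float32)
            d, g = self.convs[i].backward(d, need_dx=(i > 0))
            grads_rev.extend(reversed(g))
        grads = list(reversed(grads_rev))
        self.opt.step(self.parameters(), grads)
        self._relu_masks = None
        return loss

    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in (*self.convs, self.fc1, self.fc2):
            out.extend(layer.params)
        return out
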