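"""Minimal 1-D convolutional network layers with explicit backprop.

Everything runs on NumPy in float32.  Layers cache what they need during
``forward`` and return input gradients from ``backward`` while accumulating
parameter gradients in place.  The design is deliberately small: just the
pieces the encoder-decoder generator and the patch critic require
(strided reflection-padded convolutions, leaky/plain rectifiers, tanh,
nearest-neighbour upsampling, dropout, a dense head) plus an Adam optimizer
and global gradient-norm clipping.

Strided convolutions use ceil-mode length (``out = ceil(L / stride)``) with
symmetric reflection padding, so signal lengths that are not powers of two
(e.g. 5000 samples) pass through a 6-level stride-2 ladder cleanly.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self):
        self.grad[...] = 0.0


def _reflect_pad(x: np.ndarray, left: int, right: int) -> np.ndarray:
    if left == 0 and right == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (left, right)), mode="reflect")


def _reflect_pad_backward(gp: np.ndarray, left: int, right: int,
                          length: int) -> np.ndarray:
    """Fold gradients of a reflect-padded array back onto the original."""
    g = gp[:, :, left:left + length].copy()
    if left:
        # padded position p (0..left-1) mirrors original index left-p
        g[:, :, 1:left + 1] += gp[:, :, left - 1::-1]
    if right:
        # padded position left+length+j mirrors original index length-2-j
        g[:, :, length - 1 - right:length - 1] += gp[:, :, left + length:left + length + right][:, :, ::-1]
    return g


class Conv1d:
    """Reflection-padded 1-D convolution, ceil-mode output length."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 rng: Optional[np.random.Generator] = None,
                 weight_scale: Optional[float] = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        if weight_scale is None:
            weight_scale = math.sqrt(2.0 / (c_in * kernel))  # He-style
        self.kernel = kernel
        self.stride = stride
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(weight_scale * rng.standard_normal((c_out, c_in, kernel)))
        self.b = Param(np.zeros(c_out))
        self._cache = None

    @property
    def params(self) -> List[Param]:
        return [self.w, self.b]

    def n_params(self) -> int:
        return self.w.value.size + self.b.value.size

    def _pad_amounts(self, length: int):
        out = -(-length // self.stride)
        total = max(0, (out - 1) * self.stride + self.kernel - length)
        left = total // 2
        return out, left, total - left

    def _windows(self, x: np.ndarray):
        length = x.shape[2]
        out, left, right = self._pad_amounts(length)
        xp = _reflect_pad(x.astype(DTYPE, copy=False), left, right)
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride, :]
        return win, (length, left, right, out)

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        win, meta = self._windows(x)
        y = np.einsum("bcok,fck->bfo", win, self.w.value, optimize=True)
        y += self.b.value[None, :, None]
        if cache:
            self._cache = (win, meta)
        return y

    def forward_nobias(self, v: np.ndarray):
        """Convolve without bias; returns (y, windows) for directional passes."""
        win, _ = self._windows(v)
        y = np.einsum("bcok,fck->bfo", win, self.w.value, optimize=True)
        return y, win

    def _grad_input(self, gy: np.ndarray, meta) -> np.ndarray:
        length, left, right, out = meta
        gxp = np.zeros((gy.shape[0], self.c_in, length + left + right), dtype=DTYPE)
        for j in range(self.kernel):
            contrib = np.einsum("bfo,fc->bco", gy, self.w.value[:, :, j], optimize=True)
            gxp[:, :, j:j + self.stride * out:self.stride] += contrib
        return _reflect_pad_backward(gxp, left, right, length)

    def backward(self, gy: np.ndarray, accumulate: bool = True) -> np.ndarray:
        win, meta = self._cache
        gy = gy.astype(DTYPE, copy=False)
        if accumulate:
            self.w.grad += np.einsum("bfo,bcok->fck", gy, win, optimize=True)
            self.b.grad += gy.sum(axis=(0, 2))
        return self._grad_input(gy, meta)

    def accumulate_weight_grad(self, gy: np.ndarray, windows: np.ndarray):
        """Weight-only gradient from externally supplied input windows.

        Used by the gradient-penalty double-backprop, where the effective
        layer input is the frozen-mask propagated perturbation (the bias
        drops out of the directional derivative, so ``b`` is untouched).
        """
        self.w.grad += np.einsum("bfo,bcok->fck", gy.astype(DTYPE, copy=False),
                                 windows, optimize=True)


class LeakyReLU:
    def __init__(self, slope: float = 0.2):
        self.slope = DTYPE(slope)
        self.mask = None

    def forward(self, z: np.ndarray, cache: bool = True) -> np.ndarray:
        mask = np.where(z > 0, DTYPE(1.0), self.slope)
        if cache:
            self.mask = mask
        return z * mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self.mask


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh:
    def __init__(self):
        self.out = None

    def forward(self, z: np.ndarray, cache: bool = True) -> np.ndarray:
        out = np.tanh(z)
        if cache:
            self.out = out
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * (1.0 - self.out * self.out)


class Dropout:
    def __init__(self, p: float = 0.5):
        self.p = p
        self.mask = None

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> np.ndarray:
        if not train or self.p == 0.0:
            self.mask = None
            return x
        rng = rng if rng is not None else np.random.default_rng(0)
        keep = (rng.random(x.shape) >= self.p).astype(DTYPE) / DTYPE(1.0 - self.p)
        self.mask = keep
        return x * keep

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy if self.mask is None else gy * self.mask


class Upsample2:
    """Nearest-neighbour temporal upsampling by 2."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(x, 2, axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, c, l2 = gy.shape
        return gy.reshape(b, c, l2 // 2, 2).sum(axis=3)


class Dense:
    """Affine map on flattened features; used as the critic head."""

    def __init__(self, d_in: int, d_out: int = 1,
                 rng: Optional[np.random.Generator] = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.w = Param(rng.standard_normal((d_in, d_out)) / math.sqrt(d_in))
        self.b = Param(np.zeros(d_out))
        self._x = None

    @property
    def params(self) -> List[Param]:
        return [self.w, self.b]

    def n_params(self) -> int:
        return self.w.value.size + self.b.value.size

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        if cache:
            self._x = x.astype(DTYPE, copy=False)
        return x @ self.w.value + self.b.value

    def backward(self, gy: np.ndarray, accumulate: bool = True) -> np.ndarray:
        gy = gy.astype(DTYPE, copy=False)
        if accumulate:
            self.w.grad += self._x.T @ gy
            self.b.grad += gy.sum(axis=0)
        return gy @ self.w.value.T

    def accumulate_weight_grad(self, gy: np.ndarray, x: np.ndarray):
        self.w.grad += x.astype(DTYPE, copy=False).T @ gy.astype(DTYPE, copy=False)


def clip_grad_norm(params: Iterable[Param], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    params = list(params)
    total = math.sqrt(sum(float((p.grad.astype(np.float64) ** 2).sum()) for p in params))
    if max_norm > 0 and total > max_norm:
        scale = DTYPE(max_norm / (total + 1e-12))
        for p in params:
            p.grad *= scale
    return total


class Adam:
    def __init__(self, params: Iterable[Param], lr: float = 1e-4,
                 betas=(0.5, 0.9), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            p.value -= DTYPE(self.lr) * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


def get_state(params: Iterable[Param]) -> list:
    return [p.value.copy() for p in params]


def set_state(params: Iterable[Param], state: list):
    for p, s in zip(params, state):
        p.value[...] = s
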