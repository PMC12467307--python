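"""Spatiotemporal network layers with hand-written backward passes.

These layers operate on float32 arrays shaped (N, C, T, H, W) and implement
their own gradients (im2col convolution, batch normalisation) rather than
going through the autodiff tape — the convolutional backbone is the hot path
and benefits from BLAS matmuls over flattened patch matrices.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "GlobalAvgPool3d",
    "Sequential",
    "ResBlock3d",
]


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None

    def zero_grad(self) -> None:
        self.grad = None

    def accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g.astype(np.float32)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, int):
        return (v, v, v)
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected 3 entries, got {v!r}")
    return t


class Conv3d(Layer):
    """3D convolution via im2col; no bias (batch norm always follows)."""

    def __init__(self, in_ch: int, out_ch: int, kernel, stride=1, padding=0,
                 rng: np.random.Generator | None = None):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        fan_in = in_ch * int(np.prod(self.kernel))
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / fan_in)  # He initialisation for ReLU nets
        self.weight = Param(rng.normal(0.0, scale, size=(out_ch, in_ch, *self.kernel)))
        self._cache = None
        self._idx_cache: dict[tuple, np.ndarray] = {}

    def params(self):
        return [self.weight]

    def _out_shape(self, T, H, W):
        (kt, kh, kw), (st, sh, sw), (pt, ph, pw) = self.kernel, self.stride, self.padding
        return ((T + 2 * pt - kt) // st + 1,
                (H + 2 * ph - kh) // sh + 1,
                (W + 2 * pw - kw) // sw + 1)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 5 or x.shape[1] != self.in_ch:
            raise ValueError(f"expected (N,{self.in_ch},T,H,W) input, got shape {x.shape}")
        N, C, T, H, W = x.shape
        (kt, kh, kw), (st, sh, sw), (pt, ph, pw) = self.kernel, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
        win = sliding_window_view(xp, (kt, kh, kw), axis=(2, 3, 4))[:, :, ::st, ::sh, ::sw]
        To, Ho, Wo = win.shape[2:5]
        # rows: (n, to, ho, wo); cols: (c, kt, kh, kw)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            N * To * Ho * Wo, C * kt * kh * kw)
        wmat = self.weight.data.reshape(self.out_ch, -1)
        y = cols @ wmat.T
        if train:
            self._cache = (cols, x.shape, xp.shape, (To, Ho, Wo))
        return np.ascontiguousarray(
            y.reshape(N, To, Ho, Wo, self.out_ch).transpose(0, 4, 1, 2, 3))

    def _col2im_idx(self, xp_shape, out_shape):
        key = (xp_shape[1:], out_shape)
        if key in self._idx_cache:
            return self._idx_cache[key]
        _, C, Tp, Hp, Wp = xp_shape
        To, Ho, Wo = out_shape
        (kt, kh, kw), (st, sh, sw) = self.kernel, self.stride
        to = np.arange(To)[:, None, None, None, None, None, None] * st
        ho = np.arange(Ho)[None, :, None, None, None, None, None] * sh
        wo = np.arange(Wo)[None, None, :, None, None, None, None] * sw
        c = np.arange(C)[None, None, None, :, None, None, None]
        dt = np.arange(kt)[None, None, None, None, :, None, None]
        dh = np.arange(kh)[None, None, None, None, None, :, None]
        dw = np.arange(kw)[None, None, None, None, None, None, :]
        idx = ((c * Tp + (to + dt)) * Hp + (ho + dh)) * Wp + (wo + dw)
        idx = np.broadcast_to(idx, (To, Ho, Wo, C, kt, kh, kw)).ravel()
        self._idx_cache[key] = idx
        return idx

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, xp_shape, out_shape = self._cache
        N, C, T, H, W = x_shape
        To, Ho, Wo = out_shape
        (pt, ph, pw) = self.padding
        dym = np.ascontiguousarray(dout.transpose(0, 2, 3, 4, 1)).reshape(-1, self.out_ch)
        wmat = self.weight.data.reshape(self.out_ch, -1)
        self.weight.accum((dym.T @ cols).reshape(self.weight.data.shape))
        dcols = (dym @ wmat).reshape(N, -1)
        idx = self._col2im_idx(xp_shape, out_shape)
        size = int(np.prod(xp_shape[1:]))
        dxp = np.empty(xp_shape, dtype=np.float32)
        for n in range(N):
            dxp[n] = np.bincount(idx, weights=dcols[n].astype(np.float64),
                                 minlength=size).reshape(xp_shape[1:]).astype(np.float32)
        _, _, Tp, Hp, Wp = xp_shape
        return dxp[:, :, pt:Tp - pt or None, ph:Hp - ph or None, pw:Wp - pw or None]


class BatchNorm3d(Layer):
    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1):
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, self.ch, 1, 1, 1)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        if train:
            self._cache = (xhat, inv, x.shape)
        return (self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, x_shape = self._cache
        axes = (0, 2, 3, 4)
        shape = (1, self.ch, 1, 1, 1)
        m = dout.size / self.ch
        self.gamma.accum((dout * xhat).sum(axis=axes))
        self.beta.accum(dout.sum(axis=axes))
        dxhat = dout * self.gamma.data.reshape(shape)
        dx = (inv.reshape(shape) / m) * (
            m * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True)
        )
        return dx.astype(np.float32)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask


class GlobalAvgPool3d(Layer):
    """Mean over (T, H, W): (N, C, T, H, W) -> (N, C)."""

    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout):
        N, C, T, H, W = self._shape
        g = dout.reshape(N, C, 1, 1, 1) / float(T * H * W)
        return np.broadcast_to(g, self._shape).astype(np.float32).copy()


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class ResBlock3d(Layer):
    """Two 3x3x3 conv+BN with ReLU and an identity or projection shortcut."""

    def __init__(self, in_ch: int, out_ch: int, stride=(1, 1, 1),
                 rng: np.random.Generator | None = None):
        stride = _triple(stride)
        self.conv1 = Conv3d(in_ch, out_ch, 3, stride=stride, padding=1, rng=rng)
        self.bn1 = BatchNorm3d(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(out_ch, out_ch, 3, stride=1, padding=1, rng=rng)
        self.bn2 = BatchNorm3d(out_ch)
        self.proj = None
        if stride != (1, 1, 1) or in_ch != out_ch:
            self.proj = Sequential(
                Conv3d(in_ch, out_ch, 1, stride=stride, padding=0, rng=rng),
                BatchNorm3d(out_ch),
            )
        self._relu_mask = None

    def params(self):
        ps = (self.conv1.params() + self.bn1.params()
              + self.conv2.params() + self.bn2.params())
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x, train=False):
        y = self.bn1.forward(self.conv1.forward(x, train), train)
        y = self.relu1.forward(y, train)
        y = self.bn2.forward(self.conv2.forward(y, train), train)
        short = x if self.proj is None else self.proj.forward(x, train)
        out = y + short
        if train:
            self._relu_mask = out > 0
            return out * self._relu_mask
        return np.maximum(out, 0)

    def backward(self, dout):
        dout = dout * self._relu_mask
        dy = self.conv1.backward(self.bn1.backward(
            self.relu1.backward(self.conv2.backward(self.bn2.backward(dout)))))
        dshort = dout if self.proj is None else self.proj.backward(dout)
        return dy + dshort
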