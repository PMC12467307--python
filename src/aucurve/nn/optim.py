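"""Optimisers over mixed parameter collections (tape tensors and conv params)."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "SGD"]


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(np.asarray(p.data, dtype=np.float64)) for p in self.params]
        self.v = [np.zeros_like(np.asarray(p.data, dtype=np.float64)) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = np.asarray(p.grad, dtype=np.float64)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            upd = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.data = (p.data - upd.astype(p.data.dtype)).astype(p.data.dtype)


class SGD:
    def __init__(self, params, lr: float = 1e-2, momentum: float = 0.0):
        self.params = list(params)
        self.lr, self.momentum = lr, momentum
        self.vel = [np.zeros_like(np.asarray(p.data, dtype=np.float64)) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.vel[i] = self.momentum * self.vel[i] + np.asarray(p.grad, dtype=np.float64)
            p.data = (p.data - (self.lr * self.vel[i]).astype(p.data.dtype)).astype(p.data.dtype)
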