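"""Optimizers: AdamW (decoupled weight decay) and plain SGD."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["AdamW", "SGD"]


class AdamW:
    """Adam with decoupled weight decay.

    ``lr`` may be overridden per step (for schedules). Weight decay is not
    applied to 1-D parameters (biases, layer-norm gains/shifts), following
    the usual transformer training convention.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        # dedupe by identity so tied tensors are stepped once
        seen: set[int] = set()
        self.params = []
        for p in params:
            if id(p) not in seen:
                seen.add(id(p))
                self.params.append(p)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        if lr is None:
            lr = self.lr
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and p.data.ndim > 1:
                update = update + self.weight_decay * p.data
            p.data -= lr * update


class SGD:
    def __init__(self, params: list[Tensor], lr: float = 1e-2):
        seen: set[int] = set()
        self.params = []
        for p in params:
            if id(p) not in seen:
                seen.add(id(p))
                self.params.append(p)
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        if lr is None:
            lr = self.lr
        for p in self.params:
            if p.grad is not None:
                p.data -= lr * p.grad
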