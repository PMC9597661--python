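"""Composite differentiable functions built from the autograd primitives."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["softmax", "log_softmax", "gelu", "sigmoid", "dropout"]


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # subtracting the (detached) max is a constant shift: exact same output,
    # no gradient path needed through the max itself
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


_GELU_C = float(np.sqrt(2.0 / np.pi))


def gelu(x: Tensor) -> Tensor:
    """tanh-approximate GELU (the convention of the architecture family)."""
    inner = (x + x ** 3 * 0.044715) * _GELU_C
    return x * 0.5 * (inner.tanh() + 1.0)


def sigmoid(x: Tensor) -> Tensor:
    return 1.0 / ((-x).exp() + 1.0)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(keep)
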