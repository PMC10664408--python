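"""Minimal dense-network machinery: layers, MLPs and Adam.

The networks used here are small (a handful of dense layers), so forward and
backward passes are written directly against BLAS-backed NumPy matmuls; the
gradient of every layer is exact and unit-tested against finite differences.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Dense", "MLP", "Adam", "relu", "sigmoid"]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class Dense:
    """Affine layer ``y = act(x W + b)`` with ``act`` relu or identity."""

    W: np.ndarray
    b: np.ndarray
    activation: str = "identity"
    _x: np.ndarray | None = field(default=None, repr=False)
    _pre: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def init(cls, n_in: int, n_out: int, activation: str, rng: np.random.Generator) -> "Dense":
        # He initialisation (gain suited to ReLU; harmless for identity)
        scale = np.sqrt(2.0 / n_in)
        return cls(rng.normal(0.0, scale, size=(n_in, n_out)), np.zeros(n_out), activation)

    def forward(self, x: np.ndarray, remember: bool = False) -> np.ndarray:
        pre = x @ self.W + self.b
        if remember:
            self._x, self._pre = x, pre
        if self.activation == "relu":
            return relu(pre)
        if self.activation == "identity":
            return pre
        raise ValueError(f"unknown activation {self.activation!r}")

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        """Given dL/dy (post-activation), return dL/dx; store dL/dW, dL/db."""
        if self._x is None:
            raise RuntimeError("forward(remember=True) must precede backward")
        if self.activation == "relu":
            grad_out = grad_out * (self._pre > 0)
        self.gW = self._x.T @ grad_out
        self.gb = grad_out.sum(axis=0)
        return grad_out @ self.W.T

    def copy(self) -> "Dense":
        return Dense(self.W.copy(), self.b.copy(), self.activation)


class MLP:
    """Stack of Dense layers."""

    def __init__(self, layers: list[Dense]):
        self.layers = layers

    @classmethod
    def init(
        cls,
        sizes: list[int],
        activations: list[str],
        rng: np.random.Generator,
    ) -> "MLP":
        if len(activations) != len(sizes) - 1:
            raise ValueError("need one activation per layer")
        return cls(
            [
                Dense.init(sizes[i], sizes[i + 1], activations[i], rng)
                for i in range(len(sizes) - 1)
            ]
        )

    @property
    def sizes(self) -> list[int]:
        return [self.layers[0].W.shape[0]] + [l.W.shape[1] for l in self.layers]

    def forward(self, x: np.ndarray, remember: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, remember=remember)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def params(self) -> list[np.ndarray]:
        out = []
        for l in self.layers:
            out += [l.W, l.b]
        return out

    def grads(self) -> list[np.ndarray]:
        out = []
        for l in self.layers:
            out += [l.gW, l.gb]
        return out

    def copy(self) -> "MLP":
        return MLP([l.copy() for l in self.layers])


class Adam:
    """Adam optimiser over a fixed list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], mask: list[bool] | None = None) -> None:
        self.t += 1
        for i, (p, g) in enumerate(zip(self.params, grads)):
            if mask is not None and not mask[i]:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
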