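"""Shared trainable-layer utilities: parameter init, linear layers, Adam."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["glorot", "Linear", "Adam", "collect_parameters"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...] | None = None) -> Tensor:
    """Glorot/Xavier uniform initialization as a trainable tensor."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear:
    """Affine map x @ W + b with W of shape (d_in, d_out)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = glorot(rng, d_in, d_out)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


def collect_parameters(*modules) -> list[Tensor]:
    params: list[Tensor] = []
    for m in modules:
        if m is None:
            continue
        if isinstance(m, Tensor):
            params.append(m)
        else:
            params.extend(m.parameters())
    return params


class Adam:
    """Adam optimizer over a fixed parameter list (CPU, float64)."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
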