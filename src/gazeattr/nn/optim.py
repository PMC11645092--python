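"""Adam optimizer over Param objects."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1.0 - b1) * p.grad
            v[...] = b2 * v + (1.0 - b2) * p.grad**2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
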