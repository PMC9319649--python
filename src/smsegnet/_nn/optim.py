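"""Stochastic gradient descent with classical momentum.

Update rule per parameter: ``v <- momentum * v - lr * grad``;
``theta <- theta + v``.
"""

from __future__ import annotations

import numpy as np

from .ops import Tensor

__all__ = ["SGD"]


class SGD:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 momentum: float = 0.99):
        if lr < 0:
            raise ValueError("learning rate must be >= 0")
        self.params = params
        self.lr = float(lr)
        self.momentum = float(momentum)
        self._velocity = {k: np.zeros_like(t.data) for k, t in params.items()}

    def step(self) -> None:
        for name, t in self.params.items():
            if t.grad is None:
                continue
            v = self._velocity[name]
            v *= self.momentum
            v -= self.lr * t.grad
            t.data = t.data + v

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.zero_grad()
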