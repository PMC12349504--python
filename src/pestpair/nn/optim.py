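"""AdamW with decoupled weight decay and a cosine-annealed learning rate."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["AdamW", "cosine_lr"]


def cosine_lr(lr_init: float, step: int, total_steps: int, lr_min: float = 0.0) -> float:
    """Cosine annealing from ``lr_init`` down to ``lr_min`` over ``total_steps``."""
    if total_steps <= 1:
        return lr_init
    t = min(step, total_steps - 1) / (total_steps - 1)
    return lr_min + 0.5 * (lr_init - lr_min) * (1.0 + np.cos(np.pi * t))


class AdamW:
    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
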