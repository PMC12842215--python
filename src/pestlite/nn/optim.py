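"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["AdamW", "cosine_lr"]


class AdamW:
    """Decoupled weight-decay Adam (Loshchilov & Hutter)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def cosine_lr(epoch: float, total_epochs: int, base_lr: float,
              floor: float = 0.0) -> float:
    """Cosine annealing from ``base_lr`` at epoch 0 to ``floor`` at the end."""
    if total_epochs <= 1:
        return base_lr
    t = min(max(epoch / (total_epochs - 1), 0.0), 1.0)
    return floor + 0.5 * (base_lr - floor) * (1.0 + math.cos(math.pi * t))
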