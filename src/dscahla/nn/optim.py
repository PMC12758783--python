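"""Adadelta with L2 weight decay.

Adadelta rescales each raw gradient by the ratio of running RMS estimates of
past updates and past gradients, so step sizes adapt per parameter without a
hand-tuned global schedule.  ``eps`` seeds the update-RMS accumulator and
therefore sets the initial step scale; we default it high enough that short
CPU-scale runs make measurable progress from initialization.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Adadelta:
    def __init__(self, params: list[Tensor], lr: float = 0.01, rho: float = 0.9,
                 eps: float = 1e-2, weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.weight_decay = weight_decay
        self._acc_g = [np.zeros_like(p.data) for p in self.params]
        self._acc_dx = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, eg, edx in zip(self.params, self._acc_g, self._acc_dx):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            eg *= self.rho
            eg += (1.0 - self.rho) * g * g
            dx = np.sqrt((edx + self.eps) / (eg + self.eps)) * g
            edx *= self.rho
            edx += (1.0 - self.rho) * dx * dx
            p.data -= self.lr * dx

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most ``max_norm``."""
    total = np.sqrt(sum(float((p.grad ** 2).sum())
                        for p in params if p.grad is not None))
    if total > max_norm > 0:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total
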