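"""AdamW optimizer, gradient clipping, and warm-restart cosine schedule."""

from __future__ import annotations

import math

import numpy as np

from .layers import Parameter

__all__ = ["AdamW", "clip_grad_norm", "CosineWarmRestarts"]


class AdamW:
    """Adam with decoupled weight decay (the decay multiplies the parameter
    directly, scaled by the current learning rate, rather than entering the
    moment estimates)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self._t
        bc2 = 1.0 - b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad**2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def clip_grad_norm(params: list[Parameter], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most ``max_norm``;
    returns the pre-clip norm."""
    total = math.sqrt(sum(float(np.sum(p.grad**2)) for p in params))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            p.grad *= scale
    return total


class CosineWarmRestarts:
    """Cosine annealing with warm restarts, stepped per epoch.

    The first cycle lasts ``t0`` epochs; each subsequent cycle is ``t_mult``
    times longer.  At the start of each cycle (epochs t0, t0 + t0*t_mult,
    ...) the learning rate restarts at ``base_lr``.
    """

    def __init__(self, optimizer: AdamW, t0: int, t_mult: int = 1, eta_min: float = 0.0):
        self.optimizer = optimizer
        self.t0 = t0
        self.t_mult = t_mult
        self.eta_min = eta_min
        self.base_lr = optimizer.lr

    def lr_at(self, epoch: int) -> float:
        e, ti = epoch, self.t0
        if self.t_mult == 1:
            e = epoch % self.t0
        else:
            while e >= ti:
                e -= ti
                ti *= self.t_mult
        return self.eta_min + (self.base_lr - self.eta_min) * (1 + math.cos(math.pi * e / ti)) / 2

    def step(self, epoch: int) -> float:
        lr = self.lr_at(epoch)
        self.optimizer.lr = lr
        return lr
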