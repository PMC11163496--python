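"""AdamW optimizer and cosine-annealing learning-rate schedule."""

from __future__ import annotations

import numpy as np

from qaerr.nn.autograd import Tensor


class AdamW:
    """Adam with decoupled weight decay (Loshchilov & Hutter)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-5,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class CosineAnnealingLR:
    """Cosine decay from ``base_lr`` to ``eta_min`` over ``t_max`` epochs."""

    def __init__(self, optimizer: AdamW, t_max: int, eta_min: float = 0.0):
        self.optimizer = optimizer
        self.base_lr = optimizer.lr
        self.t_max = t_max
        self.eta_min = eta_min
        self.epoch = 0

    def lr_at(self, epoch: int) -> float:
        if self.t_max <= 1:
            return self.base_lr
        frac = min(epoch, self.t_max) / self.t_max
        return self.eta_min + 0.5 * (self.base_lr - self.eta_min) * (
            1.0 + np.cos(np.pi * frac))

    def step(self) -> None:
        self.epoch += 1
        self.optimizer.lr = self.lr_at(self.epoch)
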