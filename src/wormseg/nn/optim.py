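"""Optimizers for the numpy autograd stack."""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["AdamW"]


class AdamW:
    """Adam with decoupled weight decay (Loshchilov & Hutter).

    Update: m,v moments on the raw gradient; the weight-decay term
    ``lr * wd * theta`` is applied separately from the adaptive step.
    """

    def __init__(self, params: list[Parameter], lr: float = 2e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * (
                mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data
            )

    def zero_grad(self):
        for p in self.params:
            p.grad = None
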