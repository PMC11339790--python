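"""Adam optimizer with parameter groups (distinct learning rates)."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


class Adam:
    """Adam with L2 weight decay added to the gradient.

    `groups` is a list of dicts: {"params": [...], "lr": float}; weight decay
    and the beta/eps constants are shared across groups.
    """

    def __init__(self, groups, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        if isinstance(groups, (list, tuple)) and groups and isinstance(groups[0], Tensor):
            raise TypeError("pass parameter groups: [{'params': [...], 'lr': ...}]")
        self.groups = groups
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._state = {}

    def zero_grad(self):
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for g in self.groups:
            lr = g["lr"]
            for p in g["params"]:
                if p.grad is None:
                    continue
                grad = p.grad
                if self.wd:
                    grad = grad + self.wd * p.data
                m, v = self._state.setdefault(
                    id(p), (np.zeros_like(p.data), np.zeros_like(p.data)))
                m *= self.b1
                m += (1 - self.b1) * grad
                v *= self.b2
                v += (1 - self.b2) * grad * grad
                p.data -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
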