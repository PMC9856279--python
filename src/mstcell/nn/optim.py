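"""Adam optimizer over (parameter, gradient) array pairs."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Adam with the standard bias-corrected moment estimates.

    ``params`` is a list of (array, grad) pairs; shared (tied) arrays must
    appear only once, which :meth:`dedup` enforces by object identity.
    """

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = self.dedup(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]

    @staticmethod
    def dedup(params):
        seen, out = set(), []
        for p, g in params:
            if id(p) not in seen:
                seen.add(id(p))
                out.append((p, g))
        return out

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
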