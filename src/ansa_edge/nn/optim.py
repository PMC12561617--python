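"""Adam optimizer (Kingma & Ba) over Module parameters.

Parameters with ``requires_grad == False`` are skipped entirely, which is how
frozen base weights (low-rank adaptation, head-only fine-tuning) stay
bit-identical during training.
"""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["Adam"]


class Adam:
    """Adam, optionally with decoupled weight decay (the AdamW variant when
    ``weight_decay`` > 0)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params: list[Parameter] = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1 ** self.t)
            vhat = self._v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                p.data = p.data - self.lr * self.weight_decay * p.data

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
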