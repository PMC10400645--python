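"""Adam optimiser over the (object, attribute-name) parameter references used
by the layers in this package."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(obj, name)) for obj, name in params]
        self.v = [np.zeros_like(getattr(obj, name)) for obj, name in params]

    def step(self) -> None:
        """Apply one update using each layer's accumulated d<name> gradient."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for i, (obj, name) in enumerate(self.params):
            g = getattr(obj, "d" + name)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / c1
            vhat = self.v[i] / c2
            p = getattr(obj, name)
            setattr(obj, name, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
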