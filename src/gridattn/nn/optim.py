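"""Adam optimizer over :class:`~gridattn.nn.layers.Param` lists."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["Adam"]


class Adam:
    """Adam with optional L2 weight decay (added to the gradient).

    beta/epsilon defaults follow common deep-learning practice.
    Only ``trainable`` parameters are updated; frozen ones are left
    untouched even if gradients were (erroneously) accumulated.
    """

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if not p.trainable:
                continue
            g = p.grad
            if self.weight_decay and p.kind in ("conv_weight", "fc_weight"):
                g = g + self.weight_decay * p.value
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            mhat = self._m[i] / (1 - b1 ** self.t)
            vhat = self._v[i] / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
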