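"""Adam optimizer with configurable squared-gradient decay."""

from __future__ import annotations

import numpy as np

from ingseg.nn.layers import Parameter


class Adam:
    def __init__(
        self,
        params: list[Parameter],
        lr: float = 3e-2,
        grad_decay: float = 0.9,
        squared_grad_decay: float = 0.9,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = grad_decay
        self.beta2 = squared_grad_decay
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
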