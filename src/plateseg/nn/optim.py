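"""ADAM optimizer with the training schedule used for the segmentation nets."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    """ADAM with externally supplied per-step learning rate."""

    def __init__(
        self,
        params: list[Parameter],
        beta1: float = 1.0 - 10.0 ** -1.5,
        beta2: float = 1.0 - 10.0 ** -2.1,
        eps: float = 1e-7,
    ):
        self.params = params
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
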