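"""Adam optimizer for Sequential networks."""

from __future__ import annotations

import numpy as np

from .net import Sequential


class Adam:
    """Standard Adam with bias correction.

    ``weight_decay`` is applied as an L2 penalty on parameters whose key ends
    in ``.W`` (convolution / linear weights); biases and batch-norm affine
    parameters are left unpenalized, the usual convention.
    """

    def __init__(self, net: Sequential, lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p) for k, p, _ in net.parameters()}
        self.v = {k: np.zeros_like(p) for k, p, _ in net.parameters()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p, g in self.net.parameters():
            if self.weight_decay and k.endswith(".W"):
                g = g + self.weight_decay * p
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
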