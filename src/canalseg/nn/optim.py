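"""Optimizers: Adam (the training default) and SGD with momentum."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "SGD"]


class _Optimizer:
    def __init__(self, params):
        self.params = list(params)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam(_Optimizer):
    """Adam with optional decoupled-from-nothing classic L2 weight decay.

    The first-moment decay beta1 doubles as the "momentum" knob; weight
    decay is added to the raw gradient before the moment updates.
    """

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        super().__init__(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class SGD(_Optimizer):
    def __init__(self, params, lr: float = 1e-2, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        super().__init__(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, b in zip(self.params, self.buf):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            b *= self.momentum
            b += g
            p.data -= self.lr * b
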