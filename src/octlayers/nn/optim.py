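"""First-order optimizer used by the training loop."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Adam with L2 weight decay folded into the gradient.

    The learning rate may be changed between steps via ``set_lr`` (the
    cosine annealing schedule does exactly that).
    """

    def __init__(self, params, lr=5e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def set_lr(self, lr: float):
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
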