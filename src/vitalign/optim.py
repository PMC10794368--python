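"""Adam-family optimizers over named parameter dicts."""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError
from .tensor import Tensor


class _AdamBase:
    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        if lr <= 0:
            raise ConfigurationError(f"learning rate must be positive, got {lr}")
        self.params = params
        self.base_lr = lr
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def set_lr(self, lr: float) -> None:
        self.lr = lr


class AdamW(_AdamBase):
    """Adam with decoupled weight decay."""

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adamax(_AdamBase):
    """Adam variant using the infinity norm for the second moment."""

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = np.maximum(b2 * self.v[k], np.abs(g))
            p.data -= (self.lr / bc1) * self.m[k] / (self.v[k] + self.eps)


def make_optimizer(name: str, params: dict[str, Tensor], lr: float,
                   weight_decay: float = 0.0):
    if name == "adamw":
        return AdamW(params, lr, weight_decay=weight_decay)
    if name == "adamax":
        return Adamax(params, lr, weight_decay=weight_decay)
    raise ConfigurationError(f"unknown optimizer {name!r}")
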