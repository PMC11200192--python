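"""AdamW optimizer and loss helpers."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["AdamW", "cross_entropy", "binary_cross_entropy"]


class AdamW:
    """Decoupled weight-decay Adam (standard defaults)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under softmax logits."""
    logp = logits.log_softmax(axis=-1)
    n = logits.shape[0]
    picked = logp[np.arange(n), np.asarray(labels, dtype=int)]
    return -picked.mean()


def binary_cross_entropy(p: Tensor, labels: np.ndarray,
                         eps: float = 1e-12) -> Tensor:
    """Mean BCE of probabilities against 0/1 labels."""
    y = np.asarray(labels, dtype=float)
    p = p.reshape(-1)
    one = Tensor(np.ones_like(y))
    return -(Tensor(y) * (p + eps).log()
             + (one - Tensor(y)) * (one - p + eps).log()).mean()
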