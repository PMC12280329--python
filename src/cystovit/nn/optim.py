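"""AdamW optimizer with an optional cosine learning-rate schedule."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW", "cosine_lr"]


class AdamW:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0,
                 clip_norm: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        if self.clip_norm > 0:
            sq = sum(float((p.grad ** 2).sum()) for p in self.params
                     if p.grad is not None)
            norm = np.sqrt(sq)
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
                for p in self.params:
                    if p.grad is not None:
                        p.grad = p.grad * scale
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_lr(base_lr: float, step: int, total_steps: int,
              warmup: int = 0, floor: float = 0.0) -> float:
    """Cosine decay from ``base_lr`` to ``floor`` with linear warmup."""
    if warmup and step < warmup:
        return base_lr * (step + 1) / warmup
    if total_steps <= warmup:
        return base_lr
    frac = (step - warmup) / max(1, total_steps - warmup)
    return floor + (base_lr - floor) * 0.5 * (1.0 + np.cos(np.pi * min(frac, 1.0)))
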