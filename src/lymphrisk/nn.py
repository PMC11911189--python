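"""Small shared neural-network primitives (NumPy).

Only what the attention-MIL and fusion models need: seeded He
initialisation, overflow-safe softmax, and an Adam optimiser with decoupled
weight decay.
"""

from __future__ import annotations

import numpy as np

__all__ = ["he_init", "softmax", "stable_softmax_vec", "clip_grads", "Adam"]


def he_init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = shape[-1]
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Softmax with max-subtraction for overflow safety."""
    z = np.asarray(logits, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


# alias used where the argument is explicitly a score vector over instances
stable_softmax_vec = softmax


def clip_grads(grads: dict[str, np.ndarray], max_norm: float = 5.0) -> dict:
    """Scale the whole gradient set so its global L2 norm is <= max_norm."""
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        return {k: g * scale for k, g in grads.items()}
    return grads


class Adam:
    """Adam with decoupled weight decay; state keyed by parameter name."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            p = params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p)
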