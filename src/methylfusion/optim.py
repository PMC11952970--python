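"""Optimisers: plain SGD with L2 weight decay, and AdamW.

Both accept parameter groups so different parts of the model can train at
different learning rates and weight decays, e.g. a pre-trained encoder at a
smaller step size than freshly initialised fusion layers.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter


def _as_groups(params_or_groups, lr: float, weight_decay: float) -> list[dict]:
    if params_or_groups and isinstance(params_or_groups[0], dict):
        groups = []
        for g in params_or_groups:
            groups.append({
                "params": list(g["params"]),
                "lr": float(g.get("lr", lr)),
                "weight_decay": float(g.get("weight_decay", weight_decay)),
            })
        return groups
    return [{"params": list(params_or_groups), "lr": lr,
             "weight_decay": weight_decay}]


class SGD:
    """Stochastic gradient descent; weight decay enters the gradient (L2)."""

    def __init__(self, params, lr: float, weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.groups = _as_groups(params, lr, weight_decay)

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        for g in self.groups:
            lr, wd = g["lr"], g["weight_decay"]
            for p in g["params"]:
                if p.grad is None:
                    continue
                grad = p.grad
                if wd:
                    grad = grad + wd * p.data
                p.data -= lr * grad


class AdamW(SGD):
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        super().__init__(params, lr, weight_decay)
        self.betas = betas
        self.eps = eps
        self._state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for g in self.groups:
            lr, wd = g["lr"], g["weight_decay"]
            for p in g["params"]:
                if p.grad is None:
                    continue
                key = id(p)
                if key not in self._state:
                    self._state[key] = (np.zeros_like(p.data),
                                        np.zeros_like(p.data))
                m, v = self._state[key]
                m += (1.0 - b1) * (p.grad - m)
                v += (1.0 - b2) * (p.grad * p.grad - v)
                update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                if wd:
                    update = update + wd * p.data
                p.data -= lr * update


def prox_l21_(param: Parameter, threshold: float) -> None:
    """In-place proximal operator of ``threshold * ||W||_{2,1}``.

    Shrinks each row's Euclidean norm by ``threshold``, zeroing rows whose
    norm falls below it — the closed-form prox that makes structured row
    sparsity attainable (a subgradient step never reaches exact zeros).
    """
    norms = np.linalg.norm(param.data, axis=1, keepdims=True)
    scale = np.maximum(1.0 - threshold / np.maximum(norms, 1e-12), 0.0)
    param.data *= scale.astype(param.data.dtype)
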