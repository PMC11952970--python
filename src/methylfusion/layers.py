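"""Neural-network building blocks on top of the autodiff core.

Conventions follow the usual deep-learning ones: a ``Module`` owns
``Parameter`` leaves and sub-modules discovered by attribute introspection;
``state_dict`` / ``load_state_dict`` move weights as name -> ndarray maps;
``train()`` / ``eval()`` toggle dropout and batch-norm statistics.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Parameter, Tensor, embedding_lookup

DEFAULT_DTYPE = np.float32


class Module:
    def __init__(self) -> None:
        self.training = True

    # -- introspection --------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).items():
            pass
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    # -- modes ----------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- (de)serialisation ----------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")
            elif name.startswith("running_") and isinstance(value, np.ndarray):
                yield full, value

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own_params = dict(self.named_parameters())
        own_bufs = dict(self.named_buffers())
        for name, p in own_params.items():
            if name not in state:
                raise KeyError(f"missing parameter in checkpoint: {name}")
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint {arr.shape} "
                    f"vs model {p.data.shape}")
            p.data = arr.astype(p.data.dtype).copy()
        for name, buf in own_bufs.items():
            if name in state:
                buf[...] = np.asarray(state[name]).astype(buf.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    std = float(np.sqrt(2.0 / fan_in))
    return rng.normal(0.0, std, size=shape).astype(DEFAULT_DTYPE)


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = float(np.sqrt(6.0 / (fan_in + fan_out)))
    return rng.uniform(-limit, limit, size=shape).astype(DEFAULT_DTYPE)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_xavier(rng, in_features, out_features,
                                        (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=DEFAULT_DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(
            rng.normal(0.0, 0.02, size=(num_embeddings, dim)).astype(DEFAULT_DTYPE))

    def forward(self, ids: np.ndarray) -> Tensor:
        return embedding_lookup(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(dim, dtype=DEFAULT_DTYPE))
        self.bias = Parameter(np.zeros(dim, dtype=DEFAULT_DTYPE))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centred * inv * self.weight + self.bias


class BatchNorm1d(Module):
    """Batch normalisation over the sample axis with running statistics."""

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.weight = Parameter(np.ones(dim, dtype=DEFAULT_DTYPE))
        self.bias = Parameter(np.zeros(dim, dtype=DEFAULT_DTYPE))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(dim, dtype=DEFAULT_DTYPE)
        self.running_var = np.ones(dim, dtype=DEFAULT_DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=0, keepdims=True)
            self.running_mean += self.momentum * (
                mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (
                var.data.reshape(-1) - self.running_var)
            inv = (var + self.eps) ** -0.5
            return centred * inv * self.weight + self.bias
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return (x - self.running_mean) * inv * self.weight + self.bias


class Dropout(Module):
    """Inverted dropout driven by an explicit generator (no global state)."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits``."""
    labels = np.asarray(labels)
    logp = logits.log_softmax(axis=-1)
    picked = logp[np.arange(labels.shape[0]), labels]
    return -picked.mean()
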