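"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package's neural components (transformer encoder, fusion module,
classification head) are trained with gradients computed by this tape-based
engine. Primitives are coarse whole-array operations so that Python overhead
is negligible next to the underlying BLAS calls. Gradients are validated
against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "tensor", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- basics ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed gradient: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            # scalar fast path: NEP-50 weak promotion keeps the array dtype
            out_data = self.data + other
            if not (self.requires_grad and _GRAD_ENABLED):
                return Tensor(out_data)
            out = Tensor(out_data, True, (self,))
            out._backward = lambda g: self._accumulate(g)
            return out
        other = _as_tensor(other)
        out_data = self.data + other.data
        rg = self.requires_grad or other.requires_grad
        if not (rg and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            out_data = self.data * other
            if not (self.requires_grad and _GRAD_ENABLED):
                return Tensor(out_data)
            out = Tensor(out_data, True, (self,))
            out._backward = lambda g: self._accumulate(g * other)
            return out
        other = _as_tensor(other)
        out_data = self.data * other.data
        rg = self.requires_grad or other.requires_grad
        if not (rg and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self, other))

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = _as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = backward
        return out

    def __matmul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data @ other.data
        rg = self.requires_grad or other.requires_grad
        if not (rg and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self, other))

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = backward
        return out

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        src_shape = self.shape

        def backward(g):
            self._accumulate(g.reshape(src_shape))

        out._backward = backward
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = self.data.transpose(axes)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        inv = np.argsort(axes)

        def backward(g):
            self._accumulate(g.transpose(inv))

        out._backward = backward
        return out

    def __getitem__(self, key) -> "Tensor":
        out_data = self.data[key]
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        out._backward = backward
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else (
            np.prod([self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities -------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        out._backward = lambda g: self._accumulate(g * out_data)
        return out

    def log(self) -> "Tensor":
        out_data = np.log(self.data)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self) -> "Tensor":
        return self ** 0.5

    def abs(self) -> "Tensor":
        out_data = np.abs(self.data)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        out._backward = lambda g: self._accumulate(g * np.sign(self.data))
        return out

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - out_data * out_data))
        return out

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        out._backward = lambda g: self._accumulate(g * out_data * (1.0 - out_data))
        return out

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0.0))
        return out

    # -- fused softmax family -------------------------------------------
    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accumulate(out_data * (g - dot))

        out._backward = backward
        return out

    def log_softmax(self, axis: int = -1) -> "Tensor":
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        if not (self.requires_grad and _GRAD_ENABLED):
            return Tensor(out_data)
        out = Tensor(out_data, True, (self,))
        sm = np.exp(out_data)

        def backward(g):
            self._accumulate(g - sm * g.sum(axis=axis, keepdims=True))

        out._backward = backward
        return out


class Parameter(Tensor):
    """A trainable tensor (leaf of the graph)."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)
        # Parameters stay trainable even when created under no_grad.
        self.requires_grad = True


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def tensor(data, requires_grad: bool = False) -> Tensor:
    t = Tensor(np.asarray(data))
    t.requires_grad = requires_grad
    return t


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient routing."""
    ts = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    rg = any(t.requires_grad for t in ts)
    if not (rg and _GRAD_ENABLED):
        return Tensor(out_data)
    out = Tensor(out_data, True, ts)
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = backward
    return out


def embedding_lookup(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather ``weight[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)
    out_data = weight.data[ids]
    if not (weight.requires_grad and _GRAD_ENABLED):
        return Tensor(out_data)
    out = Tensor(out_data, True, (weight,))

    def backward(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, ids.reshape(-1), g.reshape(-1, weight.shape[-1]))
        weight._accumulate(full)

    out._backward = backward
    return out
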