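"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks in this package are small multi-layer perceptrons (widths of
order 20) combined through a handful of loss terms, so a compact tape-based
engine covering dense linear algebra, ReLU, broadcasting and reductions is
all that is required.  Gradients are accumulated by topological traversal of
the recorded expression graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter", "relu", "stack_mean"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Node in the autodiff graph wrapping a float ndarray."""

    __slots__ = ("value", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, value, parents=(), backward=None, requires_grad=False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.value.shape

    def _zero_grad_buffer(self):
        if self.grad is None:
            self.grad = np.zeros_like(self.value)

    def backward(self):
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._zero_grad_buffer()
        self.grad = self.grad + np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- operators
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.value + other.value, (self, other))

        def bw(g):
            if self.requires_grad:
                self._zero_grad_buffer()
                self.grad += _unbroadcast(g, self.value.shape)
            if other.requires_grad:
                other._zero_grad_buffer()
                other.grad += _unbroadcast(g, other.value.shape)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.value, (self,))

        def bw(g):
            if self.requires_grad:
                self._zero_grad_buffer()
                self.grad += -g

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value * other.value, (self, other))

        def bw(g):
            if self.requires_grad:
                self._zero_grad_buffer()
                self.grad += _unbroadcast(g * other.value, self.value.shape)
            if other.requires_grad:
                other._zero_grad_buffer()
                other.grad += _unbroadcast(g * self.value, other.value.shape)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.value @ other.value, (self, other))

        def bw(g):
            if self.requires_grad:
                self._zero_grad_buffer()
                if other.value.ndim == 1:
                    self.grad += np.outer(g, other.value) if self.value.ndim == 2 else g * other.value
                else:
                    gg = g if g.ndim > 1 else g[None, :]
                    upd = gg @ other.value.T
                    self.grad += upd if self.value.ndim > 1 else upd[0]
            if other.requires_grad:
                other._zero_grad_buffer()
                if self.value.ndim == 1:
                    other.grad += np.outer(self.value, g) if other.value.ndim == 2 else self.value * g
                else:
                    gg = g if g.ndim > 1 else g[:, None]
                    other.grad += self.value.T @ gg if other.value.ndim == 2 else (self.value.T @ g)

        out._backward = bw
        return out

    @property
    def T(self):
        out = Tensor(self.value.T, (self,))

        def bw(g):
            if self.requires_grad:
                self._zero_grad_buffer()
                self.grad += g.T

        out._backward = bw
        return out

    def relu(self):
        mask = self.value > 0
        out = Tensor(np.where(mask, self.value, 0.0), (self,))

        def bw(g):
            if self.requires_grad:
                self._zero_grad_buffer()
                self.grad += g * mask

        out._backward = bw
        return out

    def square(self):
        return self * self

    def sum(self, axis=None):
        out = Tensor(self.value.sum(axis=axis), (self,))

        def bw(g):
            if self.requires_grad:
                self._zero_grad_buffer()
                if axis is None:
                    self.grad += np.broadcast_to(g, self.value.shape)
                else:
                    self.grad += np.broadcast_to(np.expand_dims(g, axis), self.value.shape)

        out._backward = bw
        return out

    def mean(self, axis=None):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)

    def item(self) -> float:
        return float(self.value)


def constant(value) -> Tensor:
    return Tensor(value, requires_grad=False)


def parameter(value) -> Tensor:
    return Tensor(value, requires_grad=True)


def relu(t: Tensor) -> Tensor:
    return t.relu()


def stack_mean(tensors: list[Tensor]) -> Tensor:
    """Elementwise arithmetic mean of same-shape tensors."""
    acc = tensors[0]
    for t in tensors[1:]:
        acc = acc + t
    return acc * (1.0 / len(tensors))
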