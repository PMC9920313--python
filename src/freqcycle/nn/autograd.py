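"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training stack needs gradients through 3D convolutions, instance
normalisation, pointwise non-linearities and an FFT-magnitude representation.
This module provides a small ``Tensor`` wrapper around ``numpy.ndarray`` with
a dynamically built computation graph and reverse-mode backpropagation —
just the operations the networks in this package use, in float64.

Every op is a function producing a new ``Tensor`` whose ``_backward_fn``
maps the upstream gradient to gradients for each parent.  ``backward()``
walks the graph in reverse topological order and accumulates into ``.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum-reduce ``grad`` so it has ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward_fn = None

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # --------------------------------------------------------------- backward
    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=np.float64)

        # iterative topological sort (graphs can be deep for big networks)
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        grads = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward_fn is None:
                # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            if node._backward_fn is None:
                continue
            parent_grads = node._backward_fn(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -------------------------------------------------------------- operators
    def __add__(self, other):
        other = _as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            out._backward_fn = lambda g: (
                _unbroadcast(g, self.shape),
                _unbroadcast(g, other.shape),
            )
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            out._backward_fn = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            out._backward_fn = lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        p = float(p)
        out = _make(self.data ** p, (self,))
        if out.requires_grad:
            out._backward_fn = lambda g: (g * p * self.data ** (p - 1.0),)
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:

            def backward(g):
                g = np.asarray(g)
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                return (np.broadcast_to(g, self.shape).copy(),)

            out._backward_fn = backward
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------- pointwise
    def abs(self):
        out = _make(np.abs(self.data), (self,))
        if out.requires_grad:
            out._backward_fn = lambda g: (g * np.sign(self.data),)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = _make(y, (self,))
        if out.requires_grad:
            out._backward_fn = lambda g: (g * (1.0 - y * y),)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward_fn = lambda g: (g / self.data,)
        return out

    def exp(self):
        y = np.exp(self.data)
        out = _make(y, (self,))
        if out.requires_grad:
            out._backward_fn = lambda g: (g * y,)
        return out

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward_fn = lambda g: (g.reshape(self.shape),)
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = parents
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` (used by skip connections)."""
    tensors = [_as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            return tuple(np.split(g, splits, axis=axis))

        out._backward_fn = backward
    return out
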