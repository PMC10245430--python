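"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar result accumulates gradients
into every upstream tensor created with ``requires_grad=True``.  The op set is
exactly what the transformer stack in :mod:`torconf.network` needs — matmul,
broadcasting arithmetic, softmax building blocks, reductions, concatenation,
slicing and trigonometric maps.  All gradients are checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = parents
            out._backward = backward
            out.requires_grad = True
        return out

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative post-order DFS (graphs can be deep at long sequence length)
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.append(node)
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        grad = _unbroadcast(grad, self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._accum(g)
            other._accum(g)

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)

        return self._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __matmul__(self, other):
        other = _as_tensor(other)

        def bwd(g):
            a, b = self.data, other.data
            # promote 1-D operands to row/column matrices so the transposed
            # products below are defined, then squeeze the gradient back
            a2 = a[None, :] if a.ndim == 1 else a
            b2 = b[:, None] if b.ndim == 1 else b
            g2 = g
            if a.ndim == 1:
                g2 = np.expand_dims(g2, -2)
            if b.ndim == 1:
                g2 = np.expand_dims(g2, -1)
            ga = g2 @ np.swapaxes(b2, -1, -2)
            gb = np.swapaxes(a2, -1, -2) @ g2
            if a.ndim == 1:
                ga = ga[..., 0, :]
            if b.ndim == 1:
                gb = gb[..., 0]
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return self._make(self.data @ other.data, (self, other), bwd)

    def __pow__(self, p: float):
        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bwd)

    # -------------------------------------------------------------- pointwise
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bwd)

    def sin(self):
        def bwd(g):
            self._accum(g * np.cos(self.data))

        return self._make(np.sin(self.data), (self,), bwd)

    def cos(self):
        def bwd(g):
            self._accum(-g * np.sin(self.data))

        return self._make(np.cos(self.data), (self,), bwd)

    def sqrt(self):
        return self**0.5

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ shape moves
    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        axes = axes or tuple(range(self.ndim))[::-1]
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(self.data[idx], (self,), bwd)


def concat(tensors: list, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad or t._parents for t in tensors):
        out._parents = tuple(tensors)
        out._backward = bwd
        out.requires_grad = True
    return out


def stack(tensors: list, axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = _as_tensor(t)
        shape = list(t.data.shape)
        shape.insert(axis if axis >= 0 else t.ndim + 1 + axis, 1)
        expanded.append(t.reshape(*shape))
    return concat(expanded, axis=axis)


def softmax(x: Tensor, axis: int = -1, mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable softmax; ``mask`` entries set to False are excluded."""
    shift = x.data.max(axis=axis, keepdims=True)  # constant: no gradient needed
    z = (x - Tensor(shift)).exp()
    if mask is not None:
        z = z * Tensor(mask.astype(np.float64))
    return z / z.sum(axis=axis, keepdims=True)
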