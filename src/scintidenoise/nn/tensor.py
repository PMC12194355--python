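"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``np.ndarray`` and records, for results of
differentiable operations, the parent tensors and a closure computing the
vector-Jacobian product. ``Tensor.backward()`` runs a topological sweep and
accumulates gradients into every reachable tensor with ``requires_grad``.

Only the operations the autoencoder and its hybrid loss need are provided;
convolution-style primitives live in :mod:`scintidenoise.nn.functional`.
"""

from __future__ import annotations

import numpy as np

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._vjp = None

    # -- basic introspection -------------------------------------------------
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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            grads = node._vjp(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None:
                    continue
                if not (parent.requires_grad or parent._vjp is not None):
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data
        return from_op(out_data, (self, other), lambda g: (
            _unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)))

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data
        return from_op(out_data, (self, other), lambda g: (
            _unbroadcast(g * other.data, self.data.shape),
            _unbroadcast(g * self.data, other.data.shape)))

    __rmul__ = __mul__

    def __neg__(self):
        return from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = as_tensor(other)
        out_data = self.data - other.data
        return from_op(out_data, (self, other), lambda g: (
            _unbroadcast(g, self.data.shape), _unbroadcast(-g, other.data.shape)))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data
        return from_op(out_data, (self, other), lambda g: (
            _unbroadcast(g / other.data, self.data.shape),
            _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent
        return from_op(out_data, (self,), lambda g: (
            g * exponent * self.data ** (exponent - 1),))

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data
        return from_op(out_data, (self, other), lambda g: (
            g @ other.data.T, self.data.T @ g))

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        return from_op(np.where(mask, self.data, 0.0), (self,),
                       lambda g: (g * mask,))

    def sigmoid(self):
        # numerically stable logistic
        s = np.empty_like(self.data)
        pos = self.data >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        e = np.exp(self.data[~pos])
        s[~pos] = e / (1.0 + e)
        return from_op(s, (self,), lambda g: (g * s * (1.0 - s),))

    def sqrt(self):
        r = np.sqrt(self.data)
        return from_op(r, (self,), lambda g: (g * 0.5 / r,))

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.data.ndim for a in axes)
                for a in sorted(axes):
                    gg = np.expand_dims(gg, a)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return from_op(out_data, (self,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        return from_op(out_data, (self,),
                       lambda g: (g.reshape(self.data.shape),))

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def vjp(g):
            gx = np.zeros_like(self.data)
            gx[idx] = g
            return (gx,)

        return from_op(out_data, (self,), vjp)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def from_op(data: np.ndarray, parents: tuple, vjp) -> Tensor:
    """Build the result tensor of an op, recording the graph if needed."""
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._vjp is not None
                             for p in parents):
        out._parents = tuple(parents)
        out._vjp = vjp
    return out


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return from_op(out_data, tuple(tensors), vjp)
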