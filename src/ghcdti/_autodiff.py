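"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model in this package is small enough (a few dozen dense parameter
tensors, full-batch training) that a compact tape-based engine is all the
machinery needed.  Every operation used by the encoders, the contrastive
module and the decoder is implemented here with an explicit vector-Jacobian
product, which keeps the whole gradient path auditable and finite-difference
checkable.

Conventions
-----------
* ``Tensor.data`` is always a ``numpy.ndarray`` (float64).
* Gradients accumulate into ``Tensor.grad`` during :meth:`Tensor.backward`.
* Broadcasting follows numpy semantics; gradients are summed back over the
  broadcast axes (:func:`_unbroadcast`).
* Constant graph operators (normalized adjacencies) enter through
  :func:`spmm`, which keeps them out of the parameter tape.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None,
                 name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward
        self.name = name

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad}, name={self.name})"

    # -- autograd machinery --------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        # iterative post-order topological sort
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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

        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(_unbroadcast(-g * self.data / other.data ** 2,
                                           other.data.shape))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, _parents=(self,))
        out._backward = lambda g: self._accumulate(g.T)
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- elementwise functions ----------------------------------------------------

def _unary(x: Tensor, value: np.ndarray, local_grad: np.ndarray) -> Tensor:
    out = Tensor(value, _parents=(x,))
    out._backward = lambda g: x._accumulate(g * local_grad)
    return out


def exp(x: Tensor) -> Tensor:
    v = np.exp(x.data)
    return _unary(x, v, v)


def log(x: Tensor) -> Tensor:
    return _unary(x, np.log(x.data), 1.0 / x.data)


def sqrt(x: Tensor) -> Tensor:
    v = np.sqrt(x.data)
    return _unary(x, v, 0.5 / v)


def tanh(x: Tensor) -> Tensor:
    v = np.tanh(x.data)
    return _unary(x, v, 1.0 - v ** 2)


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def sigmoid(x: Tensor) -> Tensor:
    v = _stable_sigmoid(np.atleast_1d(np.asarray(x.data, dtype=np.float64))).reshape(x.data.shape)
    return _unary(x, v, v * (1.0 - v))


def absolute(x: Tensor) -> Tensor:
    return _unary(x, np.abs(x.data), np.sign(x.data))


def square(x: Tensor) -> Tensor:
    return _unary(x, x.data ** 2, 2.0 * x.data)


def prelu(x: Tensor, slope: Tensor) -> Tensor:
    """PReLU with a learnable (scalar or per-feature) negative slope."""
    slope = as_tensor(slope)
    neg = x.data < 0
    v = np.where(neg, slope.data * x.data, x.data)
    out = Tensor(v, _parents=(x, slope))

    def bwd(g):
        x._accumulate(g * np.where(neg, slope.data, 1.0))
        slope._accumulate(_unbroadcast(g * np.where(neg, x.data, 0.0),
                                       slope.data.shape))

    out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    out._backward = bwd
    return out


def spmm(A, X: Tensor) -> Tensor:
    """Multiply a constant (sparse or dense) operator ``A`` by tensor ``X``."""
    out_data = A @ X.data
    out = Tensor(np.asarray(out_data), _parents=(X,))
    At = A.T  # csr -> csc view; csc @ dense is as fast as csr @ dense
    out._backward = lambda g: X._accumulate(np.asarray(At @ g))
    return out


def logsumexp(x: Tensor, axis: int = 1, mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable log-sum-exp along ``axis``.

    With a binary ``mask``, entries where ``mask == 0`` are excluded (as if
    ``-inf``); every row must keep at least one active entry.
    """
    data = x.data
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any(axis=axis).all():
            raise ValueError("logsumexp mask leaves an empty row")
        data = np.where(mask, data, -np.inf)
    m = np.max(data, axis=axis, keepdims=True)
    e = np.exp(data - m)
    s = e.sum(axis=axis, keepdims=True)
    value = (m + np.log(s)).squeeze(axis=axis)
    softmax = e / s  # zero where masked
    out = Tensor(value, _parents=(x,))

    def bwd(g):
        x._accumulate(np.expand_dims(g, axis) * softmax)

    out._backward = bwd
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when ``rng`` is None (eval mode) or rate 0."""
    if rng is None or rate <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * Tensor(keep)


# -- parameters and optimization ----------------------------------------------

def glorot(rng: np.random.Generator, shape: tuple, name: str | None = None) -> Tensor:
    """Glorot-uniform initialized trainable tensor."""
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[1] if len(shape) > 1 else shape[0]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True, name=name)


def zeros(shape, name: str | None = None) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True, name=name)


class Adam:
    """Adaptive-moment estimation over a list of trainable tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
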