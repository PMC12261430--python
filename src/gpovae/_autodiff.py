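"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-based engine covering exactly the operations the variational model
needs: broadcasting arithmetic, matrix products, pointwise nonlinearities,
``lgamma`` (for the Gamma-Poisson likelihood), reductions, slicing and
concatenation.  Gradients are accumulated by topological traversal of the
operation graph; every op is verified against central finite differences in
the test suite.

Functions dispatch on type: given plain ndarrays they compute with numpy and
return ndarrays, given :class:`Tensor` they build a graph node.  Model code
is therefore written once and runs both in training (graph) and generation
(plain) mode.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"

    # -- backward pass --------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            node._backward(node.grad)


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _data(x):
    return x.data if _is_tensor(x) else np.asarray(x, dtype=np.float64)


def _accumulate(node: Tensor, grad: np.ndarray) -> None:
    if node.grad is None:
        node.grad = np.array(grad, dtype=np.float64, copy=True)
    else:
        node.grad = node.grad + grad


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _binary(a, b, fwd, da, db):
    av, bv = _data(a), _data(b)
    out_val = fwd(av, bv)
    if not (_is_tensor(a) or _is_tensor(b)):
        return out_val
    out = Tensor(out_val)
    parents = tuple(p for p in (a, b) if _is_tensor(p))
    out._parents = parents

    def backward(g):
        if _is_tensor(a):
            _accumulate(a, _unbroadcast(da(g, av, bv), av.shape))
        if _is_tensor(b):
            _accumulate(b, _unbroadcast(db(g, av, bv), bv.shape))

    out._backward = backward
    return out


def _unary(a, fwd, da):
    av = _data(a)
    out_val = fwd(av)
    if not _is_tensor(a):
        return out_val
    out = Tensor(out_val)
    out._parents = (a,)

    def backward(g):
        _accumulate(a, _unbroadcast(da(g, av, out_val), av.shape))

    out._backward = backward
    return out


# -- arithmetic ---------------------------------------------------------

def add(a, b):
    return _binary(a, b, lambda x, y: x + y, lambda g, x, y: g, lambda g, x, y: g)


def sub(a, b):
    return _binary(a, b, lambda x, y: x - y, lambda g, x, y: g, lambda g, x, y: -g)


def mul(a, b):
    return _binary(a, b, lambda x, y: x * y, lambda g, x, y: g * y, lambda g, x, y: g * x)


def div(a, b):
    return _binary(
        a, b, lambda x, y: x / y, lambda g, x, y: g / y, lambda g, x, y: -g * x / (y * y)
    )


def matmul(a, b):
    return _binary(
        a,
        b,
        lambda x, y: x @ y,
        lambda g, x, y: g @ y.T,
        lambda g, x, y: x.T @ g,
    )


# -- pointwise ----------------------------------------------------------

def exp(a):
    return _unary(a, np.exp, lambda g, x, out: g * out)


def log(a):
    return _unary(a, np.log, lambda g, x, out: g / x)


def sigmoid(a):
    return _unary(a, _sp.expit, lambda g, x, out: g * out * (1.0 - out))


def tanh(a):
    return _unary(a, np.tanh, lambda g, x, out: g * (1.0 - out * out))


def absolute(a):
    return _unary(a, np.abs, lambda g, x, out: g * np.sign(x))


def square(a):
    return _unary(a, np.square, lambda g, x, out: g * 2.0 * x)


def lgamma(a):
    return _unary(a, _sp.gammaln, lambda g, x, out: g * _sp.digamma(x))


def softplus(a):
    return _unary(
        a,
        lambda x: np.logaddexp(0.0, x),
        lambda g, x, out: g * _sp.expit(x),
    )


# -- reductions / shaping ----------------------------------------------

def sum_(a, axis=None, keepdims: bool = False):
    av = _data(a)
    out_val = av.sum(axis=axis, keepdims=keepdims)
    if not _is_tensor(a):
        return out_val
    out = Tensor(out_val)
    out._parents = (a,)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis=axis)
        _accumulate(a, np.broadcast_to(g, av.shape))

    out._backward = backward
    return out


def mean(a, axis=None, keepdims: bool = False):
    av = _data(a)
    n = av.size if axis is None else av.shape[axis]
    return div(sum_(a, axis=axis, keepdims=keepdims), float(n))


def log_softmax(a, axis: int = -1):
    av = _data(a)
    shifted = av - av.max(axis=axis, keepdims=True)
    log_z = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_val = shifted - log_z
    if not _is_tensor(a):
        return out_val
    out = Tensor(out_val)
    out._parents = (a,)
    probs = np.exp(out_val)

    def backward(g):
        _accumulate(a, g - probs * g.sum(axis=axis, keepdims=True))

    out._backward = backward
    return out


def take(a, idx):
    """Basic/advanced indexing with scatter-add backward."""
    av = _data(a)
    out_val = av[idx]
    if not _is_tensor(a):
        return out_val
    out = Tensor(out_val)
    out._parents = (a,)

    def backward(g):
        full = np.zeros_like(av)
        np.add.at(full, idx, g)
        _accumulate(a, full)

    out._backward = backward
    return out


def concat(parts, axis: int = -1):
    vals = [_data(p) for p in parts]
    out_val = np.concatenate(vals, axis=axis)
    if not any(_is_tensor(p) for p in parts):
        return out_val
    out = Tensor(out_val)
    out._parents = tuple(p for p in parts if _is_tensor(p))
    sizes = [v.shape[axis] for v in vals]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if _is_tensor(p):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                _accumulate(p, g[tuple(sl)])

    out._backward = backward
    return out


def reshape(a, shape):
    av = _data(a)
    out_val = av.reshape(shape)
    if not _is_tensor(a):
        return out_val
    out = Tensor(out_val)
    out._parents = (a,)
    out._backward = lambda g: _accumulate(a, g.reshape(av.shape))
    return out


class Adam:
    """Adaptive-moment gradient descent over a list of parameter tensors.

    Supports per-parameter learning rates via ``lr_overrides`` keyed by the
    tensor's ``name``.
    """

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 lr_overrides: dict | None = None, betas_overrides: dict | None = None):
        self.params = list(params)
        self.lr = float(lr)
        self.betas = betas
        self.eps = eps
        self.lr_overrides = dict(lr_overrides or {})
        self.betas_overrides = dict(betas_overrides or {})
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            b1, b2 = self.betas_overrides.get(p.name, self.betas)
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            m_hat = self._m[i] / (1 - b1 ** self.t)
            v_hat = self._v[i] / (1 - b2 ** self.t)
            lr = self.lr_overrides.get(p.name, self.lr)
            p.data = p.data - lr * m_hat / (np.sqrt(v_hat) + self.eps)
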