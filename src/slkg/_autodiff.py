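"""Minimal reverse-mode automatic differentiation on numpy arrays.

The encoder stages in this package are compositions of dense linear maps,
softmaxes and elementwise nonlinearities over small batched tensors. Rather
than depend on a deep-learning framework, we differentiate them with a compact
tape-based engine: a :class:`Tensor` wraps an ``ndarray`` and records the
operations applied to it; :meth:`Tensor.backward` walks the tape in reverse
topological order accumulating gradients.

Every public op in this module *dispatches*: called on plain ndarrays (or
floats) it computes with numpy directly and returns an ndarray; called with at
least one :class:`Tensor` argument it builds the differentiable graph. The
encoder code is therefore written once and serves both the training path
(Tensors) and the fast inference path (arrays).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "parameter", "constant", "is_tensor",
    "add", "sub", "mul", "div", "neg", "matmul", "power",
    "exp", "log", "sigmoid", "tanh", "relu", "softplus",
    "sum_", "mean_", "amax", "maximum", "clip",
    "concat", "stack", "reshape", "take", "put", "take_flat",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order by DFS
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(other, self)

    def __pow__(self, p):
        return power(self, p)

    def item(self):
        return float(self.data)


def parameter(data, rng: np.random.Generator | None = None, scale: float | None = None) -> Tensor:
    """Trainable tensor. If `data` is a shape tuple, Glorot-initialise it."""
    if isinstance(data, tuple):
        shape = data
        if scale is None:
            fan_in = shape[-1] if len(shape) > 1 else shape[0]
            fan_out = shape[0] if len(shape) > 1 else shape[0]
            scale = np.sqrt(2.0 / (fan_in + fan_out))
        if rng is None:
            rng = np.random.default_rng()
        data = rng.normal(0.0, scale, size=shape)
    return Tensor(data, requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _any_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _d(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else constant(np.asarray(x, dtype=np.float64))


# -- elementwise binary ------------------------------------------------------

def add(a, b):
    if not _any_tensor(a, b):
        return _d(a) + _d(b)
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def bwd(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), bwd)


def sub(a, b):
    if not _any_tensor(a, b):
        return _d(a) - _d(b)
    a, b = _wrap(a), _wrap(b)
    out_data = a.data - b.data

    def bwd(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(-g, b.data.shape))

    return _node(out_data, (a, b), bwd)


def mul(a, b):
    if not _any_tensor(a, b):
        return _d(a) * _d(b)
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def bwd(g):
        a._accum(_unbroadcast(g * b.data, a.data.shape))
        b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), bwd)


def div(a, b):
    if not _any_tensor(a, b):
        return _d(a) / _d(b)
    a, b = _wrap(a), _wrap(b)
    out_data = a.data / b.data

    def bwd(g):
        a._accum(_unbroadcast(g / b.data, a.data.shape))
        b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _node(out_data, (a, b), bwd)


def neg(a):
    if not _any_tensor(a):
        return -_d(a)
    out_data = -a.data

    def bwd(g):
        a._accum(-g)

    return _node(out_data, (a,), bwd)


def power(a, p: float):
    if not _any_tensor(a):
        return _d(a) ** p
    out_data = a.data ** p

    def bwd(g):
        a._accum(g * p * a.data ** (p - 1))

    return _node(out_data, (a,), bwd)


def matmul(a, b):
    if not _any_tensor(a, b):
        return _d(a) @ _d(b)
    a, b = _wrap(a), _wrap(b)
    out_data = a.data @ b.data

    def bwd(g):
        ad, bd = a.data, b.data
        if ad.ndim == 1 and bd.ndim == 1:  # inner product
            a._accum(g * bd)
            b._accum(g * ad)
            return
        if ad.ndim == 1:  # (k,) @ (..., k, n) -> (..., n)
            ga = (g[..., None, :] * bd).sum(axis=-1)
            a._accum(_unbroadcast(ga, ad.shape))
            gb = ad[:, None] * g[..., None, :]
            b._accum(_unbroadcast(gb, bd.shape))
            return
        if bd.ndim == 1:  # (..., m, k) @ (k,) -> (..., m)
            ga = g[..., :, None] * bd
            a._accum(_unbroadcast(ga, ad.shape))
            gb = (g[..., :, None] * ad).sum(axis=tuple(range(g.ndim - 1)) + (g.ndim - 1,))
            b._accum(_unbroadcast(gb, bd.shape))
            return
        ga = g @ np.swapaxes(bd, -1, -2)
        gb = np.swapaxes(ad, -1, -2) @ g
        a._accum(_unbroadcast(ga, ad.shape))
        b._accum(_unbroadcast(gb, bd.shape))

    return _node(out_data, (a, b), bwd)


# -- elementwise unary -------------------------------------------------------

def exp(a):
    if not _any_tensor(a):
        return np.exp(_d(a))
    out_data = np.exp(a.data)

    def bwd(g):
        a._accum(g * out_data)

    return _node(out_data, (a,), bwd)


def log(a):
    if not _any_tensor(a):
        return np.log(_d(a))
    out_data = np.log(a.data)

    def bwd(g):
        a._accum(g / a.data)

    return _node(out_data, (a,), bwd)


def sigmoid(a):
    if not _any_tensor(a):
        x = _d(a)
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out
    out_data = sigmoid(a.data)

    def bwd(g):
        a._accum(g * out_data * (1.0 - out_data))

    return _node(out_data, (a,), bwd)


def tanh(a):
    if not _any_tensor(a):
        return np.tanh(_d(a))
    out_data = np.tanh(a.data)

    def bwd(g):
        a._accum(g * (1.0 - out_data ** 2))

    return _node(out_data, (a,), bwd)


def relu(a):
    if not _any_tensor(a):
        return np.maximum(_d(a), 0.0)
    out_data = np.maximum(a.data, 0.0)

    def bwd(g):
        a._accum(g * (a.data > 0))

    return _node(out_data, (a,), bwd)


def softplus(a):
    """log(1 + exp(x)), overflow-safe; the stable primitive behind BCE."""
    if not _any_tensor(a):
        x = _d(a)
        return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    out_data = softplus(a.data)

    def bwd(g):
        a._accum(g * sigmoid(a.data))

    return _node(out_data, (a,), bwd)


def clip(a, lo: float, hi: float):
    """Clamp values; gradient passes only inside the interval."""
    if not _any_tensor(a):
        return np.clip(_d(a), lo, hi)
    out_data = np.clip(a.data, lo, hi)

    def bwd(g):
        inside = (a.data >= lo) & (a.data <= hi)
        a._accum(g * inside)

    return _node(out_data, (a,), bwd)


# -- reductions --------------------------------------------------------------

def sum_(a, axis=None, keepdims=False):
    if not _any_tensor(a):
        return _d(a).sum(axis=axis, keepdims=keepdims)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        g = np.asarray(g)
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).copy())
            return
        axes = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            for ax in sorted(ax % a.data.ndim for ax in axes):
                g = np.expand_dims(g, ax)
        a._accum(np.broadcast_to(g, a.data.shape).copy())

    return _node(out_data, (a,), bwd)


def mean_(a, axis=None, keepdims=False):
    n = _d(a).size if axis is None else np.prod(
        [_d(a).shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return div(sum_(a, axis=axis, keepdims=keepdims), float(n))


def amax(a, axis=None, keepdims=False):
    """Max-reduce; gradient routed to the first argmax along the axis."""
    if not _any_tensor(a):
        return _d(a).max(axis=axis, keepdims=keepdims)
    out_data = a.data.max(axis=axis, keepdims=keepdims)

    def bwd(g):
        g = np.asarray(g)
        full = a.data.max(axis=axis, keepdims=True)
        mask = (a.data == full)
        # first argmax only: divide by count to keep gradient well-defined on ties
        cnt = mask.sum(axis=axis, keepdims=True)
        gk = g if (axis is None or keepdims) else np.expand_dims(
            g, axis if isinstance(axis, int) else axis[0])
        if axis is None and not keepdims:
            gk = g
        a._accum(mask * gk / cnt)

    return _node(out_data, (a,), bwd)


def maximum(a, b):
    """Elementwise max of two operands; ties send gradient to the first."""
    if not _any_tensor(a, b):
        return np.maximum(_d(a), _d(b))
    a, b = _wrap(a), _wrap(b)
    out_data = np.maximum(a.data, b.data)

    def bwd(g):
        take_a = a.data >= b.data
        a._accum(_unbroadcast(g * take_a, a.data.shape))
        b._accum(_unbroadcast(g * (~take_a), b.data.shape))

    return _node(out_data, (a, b), bwd)


# -- shape & indexing --------------------------------------------------------

def reshape(a, shape):
    if not _any_tensor(a):
        return _d(a).reshape(shape)
    old = a.data.shape
    out_data = a.data.reshape(shape)

    def bwd(g):
        a._accum(g.reshape(old))

    return _node(out_data, (a,), bwd)


def concat(parts, axis=-1):
    if not _any_tensor(*parts):
        return np.concatenate([_d(p) for p in parts], axis=axis)
    parts = [_wrap(p) for p in parts]
    out_data = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.data.shape[axis] for p in parts]

    def bwd(g):
        offs = np.cumsum([0] + sizes)
        for p, lo, hi in zip(parts, offs[:-1], offs[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            p._accum(g[tuple(idx)])

    return _node(out_data, tuple(parts), bwd)


def stack(parts, axis=0):
    if not _any_tensor(*parts):
        return np.stack([_d(p) for p in parts], axis=axis)
    expanded = [reshape(p, _expand_shape(_d(p).shape, axis)) for p in parts]
    return concat(expanded, axis=axis)


def _expand_shape(shape, axis):
    shape = list(shape)
    ax = axis % (len(shape) + 1)
    shape.insert(ax, 1)
    return tuple(shape)


def take(a, indices, axis=0):
    """Row gather (embedding lookup); backward scatter-adds."""
    indices = np.asarray(indices)
    if not _any_tensor(a):
        return np.take(_d(a), indices, axis=axis)
    out_data = np.take(a.data, indices, axis=axis)

    def bwd(g):
        if a.grad is None:
            a.grad = np.zeros_like(a.data)
        if axis == 0:
            np.add.at(a.grad, indices.ravel(),
                      g.reshape((-1,) + a.data.shape[1:]))
        else:  # generic but slower path
            ga = np.zeros_like(a.data)
            np.add.at(np.moveaxis(ga, axis, 0), indices.ravel(),
                      np.moveaxis(g, axis, 0).reshape((-1,) + np.moveaxis(ga, axis, 0).shape[1:]))
            a.grad += ga

    return _node(out_data, (a,), bwd)


def take_flat(a, flat_indices):
    """Gather scalar entries by flat index from an arbitrary-shape tensor."""
    flat_indices = np.asarray(flat_indices)
    if not _any_tensor(a):
        return _d(a).ravel()[flat_indices]
    out_data = a.data.ravel()[flat_indices]

    def bwd(g):
        ga = np.zeros(a.data.size)
        np.add.at(ga, flat_indices, g)
        a._accum(ga.reshape(a.data.shape))

    return _node(out_data, (a,), bwd)


def put(values, flat_indices, shape):
    """Dense tensor of `shape` with `values` scatter-added at flat indices."""
    flat_indices = np.asarray(flat_indices)
    if not _any_tensor(values):
        out = np.zeros(int(np.prod(shape)))
        np.add.at(out, flat_indices, _d(values))
        return out.reshape(shape)
    out = np.zeros(int(np.prod(shape)))
    np.add.at(out, flat_indices, values.data)
    out_data = out.reshape(shape)

    def bwd(g):
        values._accum(g.ravel()[flat_indices])

    return _node(out_data, (values,), bwd)


# -- composite ---------------------------------------------------------------

def softmax(a, axis=-1):
    """Numerically stable softmax; the max shift is treated as a constant
    (softmax is shift-invariant so this does not change the gradient)."""
    shift = _d(a).max(axis=axis, keepdims=True)
    e = exp(sub(a, shift))
    return div(e, sum_(e, axis=axis, keepdims=True))
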