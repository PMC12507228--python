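"""Reverse-mode automatic differentiation over numpy arrays.

A small tape-free (graph-based) autodiff core in float64.  Every vector-Jacobian
product is itself expressed through the traced primitives, so gradients of
gradients are exact: calling :func:`grad` with ``create_graph=True`` returns
gradient tensors that participate in further differentiation.  This is what
makes second-order meta-gradients (differentiating an outer loss through inner
gradient-descent updates) possible without approximation.

Only the primitives required by the models in this package are provided:
broadcasted arithmetic, ``exp``/``log``/``pow``, (batched) ``matmul``,
reductions, shape ops, padding/slicing along the last axis, and an exact
gather/scatter-add adjoint pair used by the convolution lowering.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "grad",
    "add", "sub", "mul", "div", "neg", "power", "exp", "log", "sqrt",
    "matmul", "relu", "tsum", "tmean", "tmax_last",
    "reshape", "transpose", "swap_last", "broadcast_to",
    "pad_last", "slice_last", "take_last", "put_add_last",
    "softmax_last", "logsumexp_last",
]


class Tensor:
    """A numpy array plus (optionally) a backward graph node."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad=False, _parents=(), _vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._vjp = _vjp

    # -- conveniences -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # operators
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

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)


def tensor(x, requires_grad=False):
    if isinstance(x, Tensor):
        return x
    return Tensor(x, requires_grad=requires_grad)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, vjp):
    """Create a result tensor; skip graph bookkeeping for constant inputs."""
    if any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, _parents=parents, _vjp=vjp)
    return Tensor(data)


# ---------------------------------------------------------------------------
# broadcasting helpers
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum ``g`` down to ``shape`` (adjoint of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data + b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def sub(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data - b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape),
                            _unbroadcast(neg(g), b.shape)))


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data * b.data, (a, b),
                 lambda g: (_unbroadcast(mul(g, b), a.shape),
                            _unbroadcast(mul(g, a), b.shape)))


def div(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    return _node(a.data / b.data, (a, b),
                 lambda g: (_unbroadcast(div(g, b), a.shape),
                            _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape)))


def neg(a):
    a = _as_tensor(a)
    return _node(-a.data, (a,), lambda g: (neg(g),))


def power(a, p: float):
    a = _as_tensor(a)
    p = float(p)
    return _node(a.data ** p, (a,),
                 lambda g: (mul(g, mul(Tensor(p), power(a, p - 1.0))),))


def sqrt(a):
    return power(a, 0.5)


def exp(a):
    a = _as_tensor(a)
    out_data = np.exp(a.data)
    return _node(out_data, (a,), lambda g: (mul(g, exp(a)),))


def log(a):
    a = _as_tensor(a)
    return _node(np.log(a.data), (a,), lambda g: (div(g, a),))


def relu(a):
    a = _as_tensor(a)
    mask = Tensor((a.data > 0).astype(np.float64))
    return _node(a.data * mask.data, (a,), lambda g: (mul(g, mask),))


# ---------------------------------------------------------------------------
# matmul (supports numpy batched broadcasting on leading axes)
# ---------------------------------------------------------------------------

def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)

    def vjp(g):
        ga = matmul(g, transpose_last2(b))
        gb = matmul(transpose_last2(a), g)
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return _node(np.matmul(a.data, b.data), (a, b), vjp)


def transpose_last2(a):
    a = _as_tensor(a)
    axes = list(range(a.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return transpose(a, tuple(axes))


swap_last = transpose_last2


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def _norm_axis(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        return (axis % ndim,)
    return tuple(a % ndim for a in axis)


def tsum(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    axes = _norm_axis(axis, a.ndim)
    out_data = a.data.sum(axis=axes, keepdims=keepdims)
    kept_shape = tuple(1 if i in axes else s for i, s in enumerate(a.shape))

    def vjp(g):
        gg = g if keepdims else reshape(g, kept_shape)
        return (broadcast_to(gg, a.shape),)

    return _node(out_data, (a,), vjp)


def tmean(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    axes = _norm_axis(axis, a.ndim)
    n = 1
    for ax in axes:
        n *= a.shape[ax]
    return mul(tsum(a, axis=axes, keepdims=keepdims), Tensor(1.0 / n))


def tmax_last(a):
    """Max over the last axis; ties resolved to the first maximum.

    The backward pass routes the gradient through the winning position only
    (subgradient choice), so second derivatives through the mask are zero.
    """
    a = _as_tensor(a)
    idx = np.argmax(a.data, axis=-1)
    mask = np.zeros_like(a.data)
    np.put_along_axis(mask, idx[..., None], 1.0, axis=-1)
    mask_t = Tensor(mask)
    out_data = np.take_along_axis(a.data, idx[..., None], axis=-1)[..., 0]

    def vjp(g):
        return (mul(reshape(g, g.shape + (1,)), mask_t),)

    return _node(out_data, (a,), vjp)


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a, shape):
    a = _as_tensor(a)
    old = a.shape
    return _node(a.data.reshape(shape), (a,), lambda g: (reshape(g, old),))


def transpose(a, axes):
    a = _as_tensor(a)
    inv = tuple(np.argsort(axes))
    return _node(a.data.transpose(axes), (a,), lambda g: (transpose(g, inv),))


def broadcast_to(a, shape):
    a = _as_tensor(a)
    old = a.shape
    return _node(np.broadcast_to(a.data, shape).copy(), (a,),
                 lambda g: (_unbroadcast(g, old),))


# ---------------------------------------------------------------------------
# last-axis structural ops (used by the conv/pool lowering)
# ---------------------------------------------------------------------------

def pad_last(a, left: int, right: int):
    a = _as_tensor(a)
    width = [(0, 0)] * (a.ndim - 1) + [(left, right)]
    L = a.shape[-1]
    return _node(np.pad(a.data, width), (a,),
                 lambda g: (slice_last(g, left, left + L),))


def slice_last(a, start: int, stop: int):
    a = _as_tensor(a)
    L = a.shape[-1]
    return _node(a.data[..., start:stop], (a,),
                 lambda g: (pad_last(g, start, L - stop),))


def take_last(a, idx: np.ndarray):
    """Gather along the last axis with an integer index array.

    Result shape is ``a.shape[:-1] + idx.shape``.  Adjoint is
    :func:`put_add_last` (scatter-add), so the pair is exact to all orders.
    """
    a = _as_tensor(a)
    idx = np.asarray(idx)
    L = a.shape[-1]
    return _node(a.data[..., idx], (a,),
                 lambda g: (put_add_last(g, idx, L),))


def put_add_last(g, idx: np.ndarray, size: int):
    """Scatter-add ``g`` (shape ``batch + idx.shape``) into ``batch + (size,)``."""
    g = _as_tensor(g)
    idx = np.asarray(idx)
    batch_shape = g.shape[: g.ndim - idx.ndim]
    flat_idx = idx.ravel()

    gd = g.data.reshape(batch_shape + (flat_idx.size,))
    # scatter on the leading axis so np.add.at handles duplicates
    gd_t = np.moveaxis(gd, -1, 0)
    buf = np.zeros((size,) + batch_shape)
    np.add.at(buf, flat_idx, gd_t)
    out = np.moveaxis(buf, 0, -1)

    return _node(out, (g,),
                 lambda gg: (reshape(take_last(gg, idx), g.shape),))


# ---------------------------------------------------------------------------
# numerically stable composites
# ---------------------------------------------------------------------------

def logsumexp_last(a):
    a = _as_tensor(a)
    m = Tensor(np.max(a.data, axis=-1, keepdims=True))  # constant shift
    z = tsum(exp(sub(a, m)), axis=-1, keepdims=True)
    return add(log(z), m)


def softmax_last(a):
    a = _as_tensor(a)
    m = Tensor(np.max(a.data, axis=-1, keepdims=True))
    e = exp(sub(a, m))
    return div(e, tsum(e, axis=-1, keepdims=True))


# ---------------------------------------------------------------------------
# backward
# ---------------------------------------------------------------------------

def _topo(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    return order


def grad(output: Tensor, inputs, create_graph: bool = False, grad_output=None):
    """Gradients of a scalar ``output`` w.r.t. a sequence of input tensors.

    With ``create_graph=True`` the returned tensors carry their own backward
    graph, enabling higher-order differentiation.  Inputs that the output does
    not depend on receive zero gradients.
    """
    inputs = list(inputs)
    if not output.requires_grad:
        return [Tensor(np.zeros(t.shape)) for t in inputs]
    if grad_output is None:
        grad_output = Tensor(np.ones(output.shape))

    grads: dict[int, Tensor] = {id(output): _as_tensor(grad_output)}
    for node in reversed(_topo(output)):
        g = grads.pop(id(node), None)
        if g is None or node._vjp is None:
            if g is not None:
                grads[id(node)] = g
            continue
        grads[id(node)] = g  # keep for the input lookup below
        for parent, pg in zip(node._parents, node._vjp(g)):
            if pg is None or not parent.requires_grad:
                continue
            if id(parent) in grads:
                grads[id(parent)] = add(grads[id(parent)], pg)
            else:
                grads[id(parent)] = pg

    out = []
    for t in inputs:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros(t.shape))
        elif not create_graph:
            g = g.detach()
        out.append(g)
    return out
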