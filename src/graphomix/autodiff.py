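"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine records a tape of primitive operations on :class:`Tensor` objects.
Backward rules are themselves written in terms of the same primitives, so the
graph built during a backward pass is differentiable again: second derivatives
(needed for integrated-Hessians interaction scores) come from calling
:func:`grad` on the output of a previous :func:`grad` call with
``create_graph=True``.

Only the operations the package's models need are implemented: broadcasting
arithmetic, matmul, reductions, elementwise nonlinearities, indexing/scatter,
reshape/transpose/concatenate.  Everything is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "grad", "tensor", "no_grad"]


_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


class Tensor:
    """An ndarray with an optional autodiff tape entry.

    ``parents`` is a tuple of parent Tensors and ``_backward`` maps the
    upstream gradient (a Tensor) to a tuple of gradients, one per parent,
    expressed with Tensor primitives so that double backward works.
    """

    __slots__ = ("data", "requires_grad", "parents", "_backward", "grad")

    def __init__(self, data, requires_grad: bool = False,
                 parents=(), backward=None):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.parents = parents if _grad_enabled else ()
        self._backward = backward if _grad_enabled else None
        self.grad: np.ndarray | None = None

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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -_as_array(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / _as_array(other))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, e):
        return power(self, e)

    def __getitem__(self, key):
        return getitem(self, key)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes if axes else None)

    @property
    def T(self):
        return transpose(self, None)

    # -- backward ------------------------------------------------------------
    def backward(self, grad_output=None):
        """Accumulate ndarray gradients into ``.grad`` of all reachable leaves."""
        if grad_output is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad_output = np.ones_like(self.data)
        grads = grad(self, None, grad_output=Tensor(grad_output), create_graph=False,
                     _accumulate_leaves=True)
        return grads


class Parameter(Tensor):
    """A leaf tensor that is a learnable model parameter."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _make(data, parents, backward) -> Tensor:
    req = _grad_enabled and any(p.requires_grad for p in parents)
    t = Tensor(data, requires_grad=req,
               parents=parents if req else (), backward=backward if req else None)
    return t


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    ndiff = len(g.shape) - len(shape)
    if ndiff > 0:
        g = sum_(g, axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(b)

    def backward(g):
        return (_unbroadcast(g, a.shape) if a.requires_grad else None,
                _unbroadcast(g, b.shape) if b.requires_grad else None)

    return _make(a.data + b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(b)

    def backward(g):
        return (_unbroadcast(mul(g, b), a.shape) if a.requires_grad else None,
                _unbroadcast(mul(g, a), b.shape) if b.requires_grad else None)

    return _make(a.data * b.data, (a, b), backward)


def power(a, e: float) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)
    e = float(e)

    def backward(g):
        return (mul(g, mul(power(a, e - 1.0), e)),)

    return _make(np.power(a.data, e), (a,), backward)


def matmul(a, b) -> Tensor:
    """Matrix product; 2D-vs-batched cases are routed through single dgemms
    (reshape/transpose compositions) instead of numpy's slow gufunc loop."""
    a = a if isinstance(a, Tensor) else Tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(b)
    if a.ndim > 2 and b.ndim == 2:
        lead = a.shape[:-1]
        flat = reshape(a, (-1, a.shape[-1]))
        return reshape(_matmul_general(flat, b), lead + (b.shape[-1],))
    if a.ndim == 2 and b.ndim > 2:
        # a (j,k) @ b (..., k, m): move k to front, one dgemm, move j back
        batch = b.shape[:-2]
        k, m = b.shape[-2], b.shape[-1]
        nb = len(batch)
        bt = transpose(b, (nb,) + tuple(range(nb)) + (nb + 1,))  # (k, ..., m)
        o = _matmul_general(a, reshape(bt, (k, -1)))             # (j, prod)
        o = reshape(o, (a.shape[0],) + batch + (m,))
        return transpose(o, tuple(range(1, nb + 1)) + (0, nb + 1))
    return _matmul_general(a, b)


def _matmul_general(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        ga = gb = None
        if a.requires_grad:
            if a.ndim == 2 and g.ndim > 2:
                # sum over batch: a (j,k); ga[j,k] = sum_B g[B,j,m] b[B,k,m]
                nb = g.ndim - 2
                g2 = reshape(transpose(g, (nb,) + tuple(range(nb)) + (nb + 1,)),
                             (a.shape[0], -1))
                b2 = reshape(transpose(b, (nb,) + tuple(range(nb)) + (nb + 1,)),
                             (a.shape[1], -1))
                ga = _matmul_general(g2, transpose(b2))
            else:
                ga = _unbroadcast(matmul(g, _swap_last(b)), a.shape)
        if b.requires_grad:
            gb = _unbroadcast(matmul(_swap_last(a), g), b.shape)
        return ga, gb

    return _make(a.data @ b.data, (a, b), backward)


def _swap_last(t: Tensor) -> Tensor:
    axes = list(range(t.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return transpose(t, tuple(axes))


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)
    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis % a.ndim,)
    else:
        axes = tuple(ax % a.ndim for ax in axis)

    def backward(g):
        if not keepdims:
            shape = list(a.shape)
            for ax in axes:
                shape[ax] = 1
            g = reshape(g, tuple(shape))
        return (broadcast_to(g, a.shape),)

    return _make(a.data.sum(axis=axes if axis is not None else None, keepdims=keepdims),
                 (a,), backward)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)
    if axis is None:
        n = a.size
    elif isinstance(axis, int):
        n = a.shape[axis % a.ndim]
    else:
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axis]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def broadcast_to(a: Tensor, shape: tuple) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)
    if a.shape == tuple(shape):
        return a

    def backward(g):
        return (_unbroadcast(g, a.shape),)

    return _make(np.broadcast_to(a.data, shape), (a,), backward)


def reshape(a: Tensor, shape: tuple) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)

    def backward(g):
        return (reshape(g, a.shape),)

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a: Tensor, axes=None) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inv = tuple(np.argsort(axes))

    def backward(g):
        return (transpose(g, inv),)

    return _make(a.data.transpose(axes), (a,), backward)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    axis = axis % tensors[0].ndim
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        outs = []
        for i, t in enumerate(tensors):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            outs.append(getitem(g, tuple(sl)))
        return tuple(outs)

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def getitem(a: Tensor, key) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)

    def backward(g):
        return (scatter(g, key, a.shape),)

    return _make(a.data[key], (a,), backward)


def scatter(g: Tensor, key, shape: tuple) -> Tensor:
    """Adjoint of getitem: place ``g`` into zeros of ``shape`` at ``key`` (add-at)."""
    g = g if isinstance(g, Tensor) else Tensor(g)

    def backward(up):
        return (getitem(up, key),)

    out = np.zeros(shape, dtype=np.float64)
    np.add.at(out, key, g.data)
    return _make(out, (g,), backward)


# -- elementwise nonlinearities ---------------------------------------------

def exp(a) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)

    # recompute in backward: capturing the output Tensor would create a
    # reference cycle (node -> closure -> node) and delay tape reclamation
    def backward(g):
        return (mul(g, exp(a)),)

    return _make(np.exp(np.clip(a.data, -700.0, 700.0)), (a,), backward)


def log(a) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)

    def backward(g):
        return (mul(g, power(a, -1.0)),)

    return _make(np.log(a.data), (a,), backward)


def relu(a) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)
    mask = (a.data > 0).astype(np.float64)

    def backward(g):
        return (mul(g, mask),)

    return _make(a.data * mask, (a,), backward)


def abs_(a) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)
    sign = np.sign(a.data)

    def backward(g):
        return (mul(g, sign),)

    return _make(np.abs(a.data), (a,), backward)


def tanh(a) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)

    def backward(g):
        t = tanh(a)
        return (mul(g, add(mul(mul(t, t), -1.0), 1.0)),)

    return _make(np.tanh(a.data), (a,), backward)


def sigmoid(a) -> Tensor:
    a = a if isinstance(a, Tensor) else Tensor(a)

    def backward(g):
        s = sigmoid(a)
        return (mul(g, mul(s, add(mul(s, -1.0), 1.0))),)

    return _make(1.0 / (1.0 + np.exp(-np.clip(a.data, -700.0, 700.0))),
                 (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    shift = np.max(a.data, axis=axis, keepdims=True)  # constant: no gradient
    e = exp(add(a, -shift))
    return mul(e, power(sum_(e, axis=axis, keepdims=True), -1.0))


def log_softmax(a: Tensor, axis: int = -1) -> Tensor:
    shift = np.max(a.data, axis=axis, keepdims=True)
    z = add(a, -shift)
    return add(z, mul(log(sum_(exp(z), axis=axis, keepdims=True)), -1.0))


# ---------------------------------------------------------------------------
# grad
# ---------------------------------------------------------------------------

def _toposort(root: Tensor):
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order  # children appear after parents; reverse for backprop


def grad(output: Tensor, inputs, grad_output: Tensor | None = None,
         create_graph: bool = False, _accumulate_leaves: bool = False):
    """Gradients of ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own tape and
    can be differentiated again.
    """
    global _grad_enabled
    if grad_output is None:
        grad_output = Tensor(np.ones_like(output.data))
    gmap: dict[int, Tensor] = {id(output): grad_output}
    order = _toposort(output)

    prev = _grad_enabled
    _grad_enabled = create_graph
    try:
        for node in reversed(order):
            g = gmap.pop(id(node), None)
            if g is None or node._backward is None:
                if g is not None and _accumulate_leaves and node.requires_grad \
                        and not node.parents:
                    node.grad = g.data if node.grad is None else node.grad + g.data
                if g is not None and inputs is not None:
                    gmap[id(node)] = g  # keep for requested inputs
                continue
            if inputs is not None and any(node is x for x in inputs):
                gmap[id(node)] = g  # an input may be an interior node
            parent_grads = node._backward(g)
            for p, pg in zip(node.parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in gmap:
                    gmap[id(p)] = add(gmap[id(p)], pg)
                else:
                    gmap[id(p)] = pg
            if _accumulate_leaves and node.requires_grad and not node.parents:
                node.grad = g.data if node.grad is None else node.grad + g.data
    finally:
        _grad_enabled = prev

    if inputs is None:
        return None
    results = []
    for x in inputs:
        gx = gmap.get(id(x))
        if gx is None:
            gx = Tensor(np.zeros_like(x.data))
        if not create_graph:
            gx = gx.detach()
        results.append(gx)
    return results
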