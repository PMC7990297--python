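"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the ELBO of the mortality models needs:
broadcasting arithmetic, exp/log/tanh/sqrt, reductions, cumulative sums and
products, (batched) matrix products, slicing, concatenation, reshaping and a
log-determinant primitive for symmetric positive-definite matrices. Gradients
are accumulated by a single reverse sweep over a topologically sorted tape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Var", "grad", "concatenate", "logdet_psd"]


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    # sum away prepended axes
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


class Var:
    """A node in the computation graph holding a float ndarray."""

    __slots__ = ("value", "parents")

    # make numpy defer to Var's reflected operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, value, parents=()):
        self.value = np.asarray(value, dtype=float)
        self.parents = parents

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Var(shape={self.value.shape})"

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        if isinstance(other, Var):
            v = self.value + other.value
            return Var(v, ((self, lambda g, s=self.shape: _unbroadcast(g, s)),
                           (other, lambda g, s=other.shape: _unbroadcast(g, s))))
        c = np.asarray(other, dtype=float)
        return Var(self.value + c, ((self, lambda g, s=self.shape: _unbroadcast(g, s)),))

    __radd__ = __add__

    def __neg__(self):
        return Var(-self.value, ((self, lambda g: -g),))

    def __sub__(self, other):
        if isinstance(other, Var):
            return Var(self.value - other.value,
                       ((self, lambda g, s=self.shape: _unbroadcast(g, s)),
                        (other, lambda g, s=other.shape: -_unbroadcast(g, s))))
        c = np.asarray(other, dtype=float)
        return Var(self.value - c, ((self, lambda g, s=self.shape: _unbroadcast(g, s)),))

    def __rsub__(self, other):
        c = np.asarray(other, dtype=float)
        return Var(c - self.value, ((self, lambda g, s=self.shape: -_unbroadcast(g, s)),))

    def __mul__(self, other):
        if isinstance(other, Var):
            return Var(self.value * other.value,
                       ((self, lambda g, o=other.value, s=self.shape: _unbroadcast(g * o, s)),
                        (other, lambda g, o=self.value, s=other.shape: _unbroadcast(g * o, s))))
        c = np.asarray(other, dtype=float)
        return Var(self.value * c, ((self, lambda g, s=self.shape: _unbroadcast(g * c, s)),))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Var):
            return Var(self.value / other.value,
                       ((self, lambda g, o=other.value, s=self.shape: _unbroadcast(g / o, s)),
                        (other, lambda g, a=self.value, o=other.value, s=other.shape:
                            _unbroadcast(-g * a / (o * o), s))))
        c = np.asarray(other, dtype=float)
        return Var(self.value / c, ((self, lambda g, s=self.shape: _unbroadcast(g / c, s)),))

    def __rtruediv__(self, other):
        c = np.asarray(other, dtype=float)
        return Var(c / self.value,
                   ((self, lambda g, v=self.value, s=self.shape:
                       _unbroadcast(-g * c / (v * v), s)),))

    def __pow__(self, k):
        k = float(k)
        return Var(self.value ** k,
                   ((self, lambda g, v=self.value: g * k * v ** (k - 1.0)),))

    def __matmul__(self, other):
        assert isinstance(other, Var) or isinstance(other, np.ndarray)
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(other, self)

    def __getitem__(self, idx):
        v = self.value[idx]

        def vjp(g, idx=idx, shape=self.shape):
            out = np.zeros(shape)
            np.add.at(out, idx, g)
            return out

        return Var(v, ((self, vjp),))

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Var(self.value.reshape(shape),
                   ((self, lambda g, s=self.shape: g.reshape(s)),))

    def transpose(self, axes):
        inv = np.argsort(axes)
        return Var(self.value.transpose(axes),
                   ((self, lambda g: g.transpose(inv)),))

    # -- elementwise functions -----------------------------------------
    def exp(self):
        v = np.exp(self.value)
        return Var(v, ((self, lambda g: g * v),))

    def log(self):
        return Var(np.log(self.value), ((self, lambda g, v=self.value: g / v),))

    def tanh(self):
        v = np.tanh(self.value)
        return Var(v, ((self, lambda g: g * (1.0 - v * v)),))

    def sqrt(self):
        v = np.sqrt(self.value)
        return Var(v, ((self, lambda g: g * 0.5 / v),))

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        v = self.value.sum(axis=axis, keepdims=keepdims)

        def vjp(g, axis=axis, keepdims=keepdims, shape=self.shape):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, shape).copy()

        return Var(v, ((self, vjp),))

    def cumsum(self, axis):
        return Var(np.cumsum(self.value, axis=axis),
                   ((self, lambda g, a=axis: np.flip(np.cumsum(np.flip(g, a), a), a)),))

    def cumprod(self, axis):
        # valid only for inputs with no zeros (all uses here are > 0)
        v = np.cumprod(self.value, axis=axis)

        def vjp(g, a=axis, x=self.value, y=v):
            return np.flip(np.cumsum(np.flip(g * y, a), a), a) / x

        return Var(v, ((self, vjp),))


def matmul(a, b):
    """Matrix product with numpy batch broadcasting; operands ndim >= 2."""
    av = a.value if isinstance(a, Var) else np.asarray(a, dtype=float)
    bv = b.value if isinstance(b, Var) else np.asarray(b, dtype=float)
    v = np.matmul(av, bv)
    parents = []
    if isinstance(a, Var):
        parents.append((a, lambda g: _unbroadcast(np.matmul(g, np.swapaxes(bv, -1, -2)),
                                                  av.shape)))
    if isinstance(b, Var):
        parents.append((b, lambda g: _unbroadcast(np.matmul(np.swapaxes(av, -1, -2), g),
                                                  bv.shape)))
    return Var(v, tuple(parents))


def concatenate(parts, axis=0):
    arrs, parents, sizes = [], [], []
    for p in parts:
        arrs.append(p.value if isinstance(p, Var) else np.asarray(p, dtype=float))
        sizes.append(arrs[-1].shape[axis])
    v = np.concatenate(arrs, axis=axis)
    offsets = np.cumsum([0] + sizes)
    for i, p in enumerate(parts):
        if isinstance(p, Var):
            lo, hi = offsets[i], offsets[i + 1]

            def vjp(g, lo=lo, hi=hi, axis=axis):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                return g[tuple(sl)]

            parents.append((p, vjp))
    return Var(v, tuple(parents))


def solve(a, b):
    """X = A^{-1} B with batched square A; gradients via the adjoint solves."""
    av = a.value if isinstance(a, Var) else np.asarray(a, dtype=float)
    bv = b.value if isinstance(b, Var) else np.asarray(b, dtype=float)
    x = np.linalg.solve(av, bv)
    at = np.swapaxes(av, -1, -2)
    parents = []
    if isinstance(b, Var):
        parents.append((b, lambda g: _unbroadcast(np.linalg.solve(at, g), bv.shape)))
    if isinstance(a, Var):
        def vjp_a(g):
            gb = np.linalg.solve(at, g)
            return _unbroadcast(-np.matmul(gb, np.swapaxes(x, -1, -2)), av.shape)
        parents.append((a, vjp_a))
    return Var(x, tuple(parents))


def logdet_psd(m: Var) -> Var:
    """log|M| for a symmetric positive-definite matrix via Cholesky."""
    chol = np.linalg.cholesky(m.value)
    v = 2.0 * np.sum(np.log(np.diag(chol)))
    inv = np.linalg.inv(m.value)
    return Var(v, ((m, lambda g: g * inv),))


def _topo(root: Var):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node.parents:
            if id(parent) not in seen:
                stack.append((parent, False))
    return order  # parents before children


def grad(out: Var, inputs):
    """Gradient of scalar ``out`` with respect to each Var in ``inputs``."""
    assert out.value.ndim == 0 or out.value.size == 1
    grads = {id(out): np.ones_like(out.value)}
    for node in reversed(_topo(out)):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        for parent, vjp in node.parents:
            pg = vjp(g)
            key = id(parent)
            if key in grads:
                grads[key] = grads[key] + pg
            else:
                grads[key] = pg
        # keep gradients of requested leaves
        if node in inputs:
            grads[id(node)] = g
    return [grads.get(id(x), np.zeros_like(x.value)) for x in inputs]
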