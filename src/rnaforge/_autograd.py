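"""Minimal reverse-mode automatic differentiation over numpy arrays.

The toolkit's neural components (language model, transformer blocks, structure
module) and its differentiable losses (gFAPE, distogram cross-entropy, the
consensus optimization objective) all run on this engine.  It supports exactly
the operator set those components need: broadcasting arithmetic, elementwise
transcendentals, reductions, ``einsum``, basic indexing, softmax and
concatenation.  Gradients are accumulated by topological traversal of the
recorded operation graph.

Design notes
------------
* Arrays keep whatever float dtype they come in with (float32 for network
  training, float64 for geometry/optimization where gradient checks demand
  precision).
* Graph recording can be switched off globally with :class:`no_grad`; forward
  passes in inference mode then carry no overhead beyond the array math.
* Broadcasting in binary ops is undone in the backward pass by summing the
  incoming gradient over broadcast axes (``_unbroadcast``).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled", "einsum", "concatenate", "stack", "maximum", "minimum", "where"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    def __init__(self, data, requires_grad: bool = False, parents=(), bw=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._bw = bw

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(np.asarray(data), requires_grad=True)

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
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    @staticmethod
    def _make(data, parents, bw):
        track = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        if not track:
            return Tensor(data, requires_grad=False)
        return Tensor(data, requires_grad=True, parents=parents, bw=bw)

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order via iterative post-order DFS
        topo, seen = [], set()
        work = [(self, False)]
        while work:
            node, done = work.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            work.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    work.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None or t._bw is None:
                continue
            for p, pg in zip(t._parents, t._bw(g)):
                if pg is None or not p.requires_grad:
                    continue
                pg = np.asarray(pg, dtype=p.data.dtype)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg
                if p._bw is None:  # leaf
                    p.grad = grads[id(p)]

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        o = _as_tensor(other)
        out_data = self.data + o.data
        return Tensor._make(out_data, (self, o), lambda g: (
            _unbroadcast(g, self.data.shape), _unbroadcast(g, o.data.shape)))

    __radd__ = __add__

    def __sub__(self, other):
        o = _as_tensor(other)
        return Tensor._make(self.data - o.data, (self, o), lambda g: (
            _unbroadcast(g, self.data.shape), _unbroadcast(-g, o.data.shape)))

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __mul__(self, other):
        o = _as_tensor(other)
        a, b = self.data, o.data
        return Tensor._make(a * b, (self, o), lambda g: (
            _unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = _as_tensor(other)
        a, b = self.data, o.data
        return Tensor._make(a / b, (self, o), lambda g: (
            _unbroadcast(g / b, a.shape), _unbroadcast(-g * a / (b * b), b.shape)))

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p):
        assert np.isscalar(p)
        a = self.data
        return Tensor._make(a ** p, (self,), lambda g: (g * p * a ** (p - 1),))

    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self):
        a = self.data
        return Tensor._make(np.log(a), (self,), lambda g: (g / a,))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, (self,), lambda g: (g / (2.0 * out),))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._make(out, (self,), lambda g: (g * (1.0 - out * out),))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out, (self,), lambda g: (g * out * (1.0 - out),))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def softplus(self):
        a = self.data
        out = np.logaddexp(0.0, a)
        sig = 1.0 / (1.0 + np.exp(-a))
        return Tensor._make(out, (self,), lambda g: (g * sig,))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self.data
        out = a.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis if isinstance(axis, (int,)) else tuple(axis))
            return (np.broadcast_to(gg, a.shape),)

        return Tensor._make(out, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a_shape = self.data.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(a_shape),))

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(inv),))

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        a = self.data

        def bw(g):
            out = np.zeros_like(a)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(a[idx], (self,), bw)

    # -- contractions ---------------------------------------------------------
    def __matmul__(self, other):
        o = _as_tensor(other)
        a, b = self.data, o.data
        out = a @ b

        def bw(g):
            if a.ndim == 1 and b.ndim == 1:
                return (g * b, g * a)
            if b.ndim == 1:
                return (np.expand_dims(g, -1) * b, _unbroadcast(
                    (a * np.expand_dims(g, -1)).reshape(-1, a.shape[-1]).sum(0), b.shape))
            if a.ndim == 1:
                return ((g[..., None, :] * b).sum(-1).reshape(a.shape), np.outer(a, g))
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._make(out, (self, o), bw)


def einsum(spec: str, *ops) -> Tensor:
    """Autodiff-aware ``np.einsum``.

    Restricted to explicit specs (``->`` present) without repeated indices
    within one operand; every input index must appear in the output or in
    another operand (true of all contractions used in this package).
    """
    tensors = [_as_tensor(o) for o in ops]
    arrays = [t.data for t in tensors]
    out = np.einsum(spec, *arrays)
    lhs, rhs = spec.split("->")
    in_specs = lhs.split(",")

    def bw(g):
        grads = []
        for i, ispec in enumerate(in_specs):
            others = [(s, arrays[j]) for j, s in enumerate(in_specs) if j != i]
            specs = [rhs] + [s for s, _ in others]
            arrs = [g] + [a for _, a in others]
            # indices of operand i that are nowhere else: sum them in via broadcast
            known = set("".join(specs))
            missing = [c for c in ispec if c not in known]
            target = ispec
            if missing:
                reduced = "".join(c for c in ispec if c not in missing)
                gi = np.einsum(",".join(specs) + "->" + reduced, *arrs)
                # broadcast to full operand shape
                shape = [arrays[i].shape[ispec.index(c)] for c in ispec]
                expand = gi
                for c in missing:
                    expand = np.expand_dims(expand, -1)
                order = [c for c in ispec if c not in missing] + missing
                perm = [order.index(c) for c in ispec]
                gi = np.broadcast_to(expand, [arrays[i].shape[ispec.index(c)] for c in order]).transpose(perm)
                grads.append(np.ascontiguousarray(gi))
            else:
                grads.append(np.einsum(",".join(specs) + "->" + target, *arrs))
        return grads

    return Tensor._make(out, tuple(tensors), bw)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    t = _as_tensor(t)
    a = t.data
    m = a.max(axis=axis, keepdims=True)
    e = np.exp(a - m)
    out = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return ((g - dot) * out,)

    return Tensor._make(out, (t,), bw)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Fused layer normalization over the last axis (single graph node)."""
    x = _as_tensor(x)
    gamma = _as_tensor(gamma)
    beta = _as_tensor(beta)
    a = x.data
    mu = a.mean(axis=-1, keepdims=True)
    cen = a - mu
    var = (cen * cen).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = cen * inv
    out = xhat * gamma.data + beta.data

    def bw(g):
        gx = g * gamma.data
        gxm = gx.mean(axis=-1, keepdims=True)
        gxx = (gx * xhat).mean(axis=-1, keepdims=True)
        dx = inv * (gx - gxm - xhat * gxx)
        dgamma = _unbroadcast(g * xhat, gamma.data.shape)
        dbeta = _unbroadcast(g, beta.data.shape)
        return dx, dgamma, dbeta

    return Tensor._make(out, (x, gamma, beta), bw)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    arrays = [t.data for t in tensors]
    out = np.concatenate(arrays, axis=axis)
    sizes = [a.shape[axis] for a in arrays]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out, tuple(tensors), bw)


def stack(tensors, axis=0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._make(out, tuple(tensors), bw)


def maximum(t, const) -> Tensor:
    """Elementwise max against a non-differentiated constant."""
    t = _as_tensor(t)
    c = np.asarray(const)
    mask = t.data > c
    return Tensor._make(np.maximum(t.data, c), (t,), lambda g: (g * mask,))


def minimum(t, const) -> Tensor:
    """Elementwise min against a non-differentiated constant (e.g. d_cut clamp)."""
    t = _as_tensor(t)
    c = np.asarray(const)
    mask = t.data < c
    return Tensor._make(np.minimum(t.data, c), (t,), lambda g: (g * mask,))


def where(cond, a, b) -> Tensor:
    cond = np.asarray(cond, dtype=bool)
    a, b = _as_tensor(a), _as_tensor(b)
    out = np.where(cond, a.data, b.data)
    return Tensor._make(out, (a, b), lambda g: (
        _unbroadcast(np.where(cond, g, 0.0), a.data.shape),
        _unbroadcast(np.where(cond, 0.0, g), b.data.shape)))
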