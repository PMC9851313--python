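"""Reverse-mode automatic differentiation over numpy arrays.

This is the numerical core the model components are built on: a small
dynamically-built computation graph whose leaves are :class:`Tensor`
parameters and whose interior nodes record a local backward rule.  Only the
operations the model actually needs are implemented (dense linear algebra,
the usual pointwise nonlinearities, concatenation/stacking, advanced
indexing, reductions).  Gradient rules are exercised against central finite
differences in the test suite.

Conventions
-----------
* ``Tensor.data`` is always a ``numpy.ndarray`` (possibly 0-d).
* ``Tensor.grad`` is ``None`` until :meth:`Tensor.backward` reaches the
  tensor; a parameter whose grad is still ``None`` after a backward pass was
  not part of the loss graph, and optimizers skip it.
* Broadcasting follows numpy; gradients of broadcast operands are summed
  back to the operand's shape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import expit as _expit

__all__ = ["Tensor", "Adam", "concat", "stack", "dropout", "glorot",
           "softmax", "segment_attention"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float64, copy=False)
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Callable | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape),
                                 dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        # iterative DFS post-order (graphs can be deep: GRU over time steps)
        visit: list[tuple[Tensor, bool]] = [(self, False)]
        while visit:
            node, processed = visit.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            visit.append((node, True))
            for p in node._parents:
                visit.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        """A view of the same data cut off from the graph (stop-gradient)."""
        return Tensor(self.data)

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(_unbroadcast(g, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(g, b.data.shape))
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                if a.requires_grad:
                    a._accum(_unbroadcast(g * b.data, a.data.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(g * a.data, b.data.shape))
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, p=p: a._accum(g * p * a.data ** (p - 1))
        return out

    def __matmul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        if out.requires_grad:
            def bwd(g, a=self, b=other):
                ad, bd = a.data, b.data
                if a.requires_grad:
                    if ad.ndim == 1 and bd.ndim == 2:       # (k,)@(k,n)->(n,)
                        a._accum(bd @ g)
                    elif ad.ndim == 2 and bd.ndim == 1:     # (m,k)@(k,)->(m,)
                        a._accum(np.outer(g, bd))
                    elif ad.ndim == 1 and bd.ndim == 1:     # dot
                        a._accum(g * bd)
                    else:                                   # (m,k)@(k,n)
                        a._accum(g @ bd.T)
                if b.requires_grad:
                    if ad.ndim == 1 and bd.ndim == 2:
                        b._accum(np.outer(ad, g))
                    elif ad.ndim == 2 and bd.ndim == 1:
                        b._accum(ad.T @ g)
                    elif ad.ndim == 1 and bd.ndim == 1:
                        b._accum(g * ad)
                    else:
                        b._accum(ad.T @ g)
            out._backward = bwd
        return out

    # -- pointwise nonlinearities ---------------------------------------

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, y=out.data: a._accum(g * y)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g / a.data)
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, y=y: a._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self) -> "Tensor":
        y = _expit(self.data)  # numerically stable logistic
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, y=y: a._accum(g * y * (1.0 - y))
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g * (a.data > 0))
        return out

    def leaky_relu(self, slope: float = 0.01) -> "Tensor":
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data),
                     parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, s=slope: a._accum(
                g * np.where(a.data > 0, 1.0, s))
        return out

    def elu(self, alpha: float = 1.0) -> "Tensor":
        y = np.where(self.data > 0, self.data, alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0))
        out = Tensor(y, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self, y=y, al=alpha: a._accum(
                g * np.where(a.data > 0, 1.0, y + al))
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(
                g * ((a.data >= lo) & (a.data <= hi)))
        return out

    # -- reductions / reshapes ------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if out.requires_grad:
            def bwd(g, a=self, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.reshape(a.data.shape))
        return out

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g, a=self: a._accum(g.T)
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))
        if out.requires_grad:
            def bwd(g, a=self, idx=idx):
                full = np.zeros_like(a.data)
                if (isinstance(idx, np.ndarray) and idx.ndim == 1
                        and idx.dtype.kind in "iu" and idx.size > 0):
                    # sort + reduceat scatter-add (faster than np.add.at)
                    order = np.argsort(idx, kind="stable")
                    sidx = idx[order]
                    starts = np.r_[0, np.flatnonzero(np.diff(sidx)) + 1]
                    full[sidx[starts]] += np.add.reduceat(g[order], starts, axis=0)
                else:
                    np.add.at(full, idx, g)
                a._accum(full)
            out._backward = bwd
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


# -- free functions ------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g, ts=tensors, splits=splits, axis=axis):
            for t, piece in zip(ts, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = bwd
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    if out.requires_grad:
        def bwd(g, ts=tensors, axis=axis):
            for k, t in enumerate(ts):
                if t.requires_grad:
                    t._accum(np.take(g, k, axis=axis))
        out._backward = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis`` (shift is detached)."""
    shift = np.max(x.data, axis=axis, keepdims=True)
    e = (x - Tensor(shift)).exp()
    return e / e.sum(axis=axis, keepdims=True)


def segment_attention(logits: Tensor, values: Tensor,
                      segments: Sequence[tuple[int, int]]) -> Tensor:
    """Row-segment softmax attention pooling, fused into one graph node.

    For each contiguous row segment [lo, hi) of ``values`` (shape (N, d)),
    computes softmax(logits[lo:hi]) and returns the attention-weighted sum
    of the segment's rows; output shape (n_segments, d).  Segments must be
    non-empty.  Equivalent to slicing per segment and composing softmax
    with a weighted sum, but with a hand-written backward pass.
    """
    L, V = logits.data, values.data
    n_seg = len(segments)
    out = np.empty((n_seg, V.shape[1]))
    alpha = np.empty(L.shape[0])
    for k, (lo, hi) in enumerate(segments):
        if hi <= lo:
            raise ValueError("empty attention segment")
        a = np.exp(L[lo:hi] - L[lo:hi].max())
        a /= a.sum()
        alpha[lo:hi] = a
        out[k] = a @ V[lo:hi]
    res = Tensor(out, parents=(logits, values))
    if res.requires_grad:
        def bwd(g, lg=logits, vl=values, segs=segments, alpha=alpha):
            dL = np.zeros_like(lg.data) if lg.requires_grad else None
            dV = np.zeros_like(vl.data) if vl.requires_grad else None
            for k, (lo, hi) in enumerate(segs):
                a = alpha[lo:hi]
                if dV is not None:
                    dV[lo:hi] = np.outer(a, g[k])
                if dL is not None:
                    da = vl.data[lo:hi] @ g[k]
                    dL[lo:hi] = a * (da - a @ da)
            if dL is not None:
                lg._accum(dL)
            if dV is not None:
                vl._accum(dV)
        res._backward = bwd
    return res


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


def glorot(rng: np.random.Generator, *shape: int) -> Tensor:
    """Glorot/Xavier-uniform initialised trainable tensor."""
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Adam:
    """Adam with decoupled behaviour for absent gradients.

    Parameters whose ``grad`` is ``None`` after a backward pass did not
    participate in the loss and are left untouched (their moment buffers do
    not advance either), so e.g. an auxiliary head excluded from the
    objective stays bit-identical to its initialization.
    """

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = [0] * len(self.params)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._t[k] += 1
            t = self._t[k]
            self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * g
            self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * g * g
            mhat = self._m[k] / (1 - self.b1 ** t)
            vhat = self._v[k] / (1 - self.b2 ** t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
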