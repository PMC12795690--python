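"""A compact reverse-mode automatic-differentiation core on numpy arrays.

Supports exactly the operations the geometric attention network needs:
broadcasting arithmetic, matmul, elementwise nonlinearities, reductions,
row gathering and segment sums (the scatter/gather pair behind neighbourhood
softmax and per-chain pooling), concatenation, and an Adam optimiser.
Floating dtypes are preserved (the network runs in float32 by default;
float64 is used where gradient checks demand it); segment reductions use
sorted ``reduceat`` which is far faster than ``ufunc.at`` scatters.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Node in the autodiff graph wrapping a floating-point ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        arr = np.asarray(data)
        self.data = arr if arr.dtype.kind == "f" else arr.astype(float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        if not isinstance(other, Tensor) and np.isscalar(other):
            # scalar fast path: no parent node, no dtype promotion
            out = Tensor(self.data + other, parents=(self,))
            if out.requires_grad:
                out._backward = lambda g: (g,)
            return out
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        if out.requires_grad:
            def bwd(g):
                return (_unbroadcast(g, self.data.shape),
                        _unbroadcast(g, other.data.shape))
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if not isinstance(other, Tensor) and np.isscalar(other):
            out = Tensor(self.data * other, parents=(self,))
            if out.requires_grad:
                out._backward = lambda g: (g * other,)
            return out
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        if out.requires_grad:
            def bwd(g):
                return (_unbroadcast(g * other.data, self.data.shape),
                        _unbroadcast(g * self.data, other.data.shape))
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if not isinstance(other, Tensor) and np.isscalar(other):
            return self * (1.0 / other)
        other = self._wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        if out.requires_grad:
            def bwd(g):
                return (_unbroadcast(g / other.data, self.data.shape),
                        _unbroadcast(-g * self.data / other.data**2, other.data.shape))
            out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        if out.requires_grad:
            def bwd(g):
                return (g @ other.data.T, self.data.T @ g)
            out._backward = bwd
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: (g * (self.data > 0),)
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: (g * out.data,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: (g / self.data,)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def sqrt(self):
        return self ** 0.5

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient passes only through the interior."""
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))
        if out.requires_grad:
            mask = (self.data > lo) & (self.data < hi)
            out._backward = lambda g: (g * mask,)
        return out

    # -- reductions & reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if out.requires_grad:
            def bwd(g):
                if axis is None:
                    return (np.broadcast_to(g, self.data.shape).copy(),)
                gg = g if keepdims else np.expand_dims(g, axis)
                return (np.broadcast_to(gg, self.data.shape).copy(),)
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        """Select rows by integer index (with repetition)."""
        idx = np.asarray(idx, int)
        out = Tensor(self.data[idx], parents=(self,))
        if out.requires_grad:
            n = self.data.shape[0]
            out._backward = lambda g: (_segment_reduce(g, idx, n, np.add, 0.0),)
        return out

    # -- misc -----------------------------------------------------------------
    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- backprop --------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            # only leaves (parameters, inputs) retain .grad; intermediate
            # gradients live transiently in the work dict to bound memory
            if not t._parents or t._backward is None:
                t.grad = g.copy() if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def affine(x: Tensor, W: Tensor, b: Tensor | None = None) -> Tensor:
    """Fused x @ W + b (single graph node; saves an intermediate per layer)."""
    data = x.data @ W.data
    if b is not None:
        data = data + b.data
    parents = (x, W) if b is None else (x, W, b)
    out = Tensor(data, parents=parents)
    if out.requires_grad:
        def bwd(g):
            gx = g @ W.data.T
            gW = x.data.T @ g
            if b is None:
                return gx, gW
            return gx, gW, _unbroadcast(g, b.data.shape)
        out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]
        out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def _segment_reduce(values: np.ndarray, segment_ids: np.ndarray,
                    num_segments: int, ufunc, fill: float) -> np.ndarray:
    """Sorted-reduceat segment reduction (much faster than ufunc.at)."""
    out = np.full((num_segments,) + values.shape[1:], fill, dtype=values.dtype)
    if len(segment_ids) == 0:
        return out
    order = np.argsort(segment_ids, kind="stable")
    seg_s = segment_ids[order]
    vals = values[order]
    counts = np.bincount(segment_ids, minlength=num_segments)
    valid = counts > 0
    # reduceat only over non-empty segments: their starts are strictly
    # increasing and < len, so spans are exactly the segment extents
    starts = np.searchsorted(seg_s, np.flatnonzero(valid))
    if len(starts):
        out[valid] = ufunc.reduceat(vals, starts, axis=0)
    return out


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `t` into `num_segments` buckets given per-row segment ids."""
    segment_ids = np.asarray(segment_ids, int)
    acc = _segment_reduce(t.data, segment_ids, num_segments, np.add, 0.0)
    out = Tensor(acc, parents=(t,))
    if out.requires_grad:
        out._backward = lambda g: (g[segment_ids],)
    return out


def segment_softmax(logits: Tensor, segment_ids: np.ndarray,
                    num_segments: int) -> Tensor:
    """Channel-wise softmax of edge logits over each target segment.

    Fused single graph node with the analytic softmax backward
    da_i = a_i * (g_i - sum_j a_j g_j) taken per segment and channel.
    """
    segment_ids = np.asarray(segment_ids, int)
    m = _segment_reduce(logits.data, segment_ids, num_segments, np.maximum, -np.inf)
    e = np.exp(logits.data - m[segment_ids])
    denom = _segment_reduce(e, segment_ids, num_segments, np.add, 0.0)
    a = e / denom[segment_ids]
    out = Tensor(a, parents=(logits,))
    if out.requires_grad:
        def bwd(g):
            dot = _segment_reduce(g * a, segment_ids, num_segments, np.add, 0.0)
            return ((g - dot[segment_ids]) * a,)
        out._backward = bwd
    return out


def mlp2(x: Tensor, W1: Tensor, b1: Tensor, W2: Tensor, b2: Tensor) -> Tensor:
    """Fused two-layer perceptron W2 @ relu(W1 x + b1) + b2 as one graph node.

    Stores only the hidden pre-activation, cutting the per-edge temporaries
    that dominate memory traffic on large edge sets.
    """
    h_pre = x.data @ W1.data + b1.data
    h = np.maximum(h_pre, 0.0)
    out = Tensor(h @ W2.data + b2.data, parents=(x, W1, b1, W2, b2))
    if out.requires_grad:
        def bwd(g):
            gW2 = h.T @ g
            gb2 = g.sum(axis=0)
            gh = g @ W2.data.T
            gh *= h_pre > 0
            return (gh @ W1.data.T, x.data.T @ gh, gh.sum(axis=0), gW2, gb2)
        out._backward = bwd
    return out


def segment_mean_np(values: np.ndarray, segment_ids: np.ndarray,
                    num_segments: int) -> np.ndarray:
    """Plain-numpy segment mean (no gradients) for oracles and bookkeeping."""
    acc = np.zeros((num_segments,) + values.shape[1:])
    np.add.at(acc, segment_ids, values)
    counts = np.bincount(segment_ids, minlength=num_segments).astype(float)
    counts = np.maximum(counts, 1.0)
    return acc / counts.reshape((-1,) + (1,) * (values.ndim - 1))


def dropout(t: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return t
    mask = (rng.random(t.data.shape) >= p).astype(t.data.dtype) * (1.0 / (1.0 - p))
    return t * Tensor(mask)


class Parameter(Tensor):
    """Leaf tensor updated by the optimiser."""

    def __init__(self, data):
        arr = np.array(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(float)
        super().__init__(arr, requires_grad=True)


class Adam:
    """Adam optimiser over a list of :class:`Parameter`."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            upd = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            p.data = upd.astype(p.data.dtype, copy=False)
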