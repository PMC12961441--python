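"""Minimal reverse-mode automatic differentiation over numpy arrays.

The segmentation network in this package runs on CPU and is small enough
that a tape-based scalar-of-arrays engine is sufficient.  All arithmetic is
float64 so finite-difference gradient checks are meaningful at ~1e-6.

Only the operations the network actually uses are implemented: broadcasted
elementwise arithmetic, matmul, relu/sigmoid/exp/log, axis reductions,
softmax, row gathering (neighbor lookup), segment mean/max (grid pooling)
and concatenation.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "segment_mean", "segment_max",
           "set_default_dtype", "default_dtype", "precision"]

_DTYPE = np.float64


def set_default_dtype(dtype) -> type:
    """Set the engine's array dtype; returns the previous one.

    float64 (the default) is required for tight finite-difference gradient
    agreement; float32 halves memory traffic and is the documented
    single-precision training mode.
    """
    global _DTYPE
    prev = _DTYPE
    _DTYPE = np.dtype(dtype).type
    return prev


def default_dtype() -> type:
    return _DTYPE


@contextlib.contextmanager
def precision(dtype):
    prev = set_default_dtype(dtype)
    try:
        yield
    finally:
        set_default_dtype(prev)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- infrastructure -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=_DTYPE)
        # process children before parents, freeing each node's grad and
        # closure as soon as it has propagated (keeps peak memory low)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            if t._prev:
                t._backward = None
                t._prev = ()
                if t is not self:
                    t.grad = None

    # -- arithmetic ------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** (-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self ** (-1.0)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))

        out._backward = bw
        return out

    # -- nonlinearities --------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * s * (1 - s))

        out._backward = bw
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * e)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bw
        return out

    # -- reductions / reshaping -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        # ties: gradient routed to the first argmax (matches numpy argmax)
        idx = self.data.argmax(axis=axis)
        out = Tensor(out_data, _prev=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), gg, axis=axis)
            self._accum(full)

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _prev=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)

        out._backward = bw
        return out

    def broadcast_to(self, shape):
        out = Tensor(np.broadcast_to(self.data, shape), _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))

        out._backward = bw
        return out

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        out._backward = bw
        return out

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        out = Tensor(ls, _prev=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g - np.exp(ls) * g.sum(axis=axis, keepdims=True))

        out._backward = bw
        return out


def concat(tensors: list, axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """t[idx] along axis 0; idx may be any integer array shape."""
    idx = np.asarray(idx)
    out = Tensor(t.data[idx], _prev=(t,))

    def bw(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            np.add.at(full, idx, g)
            t._accum(full)

    out._backward = bw
    return out


def segment_mean(t: Tensor, seg_ids: np.ndarray, num_segments: int) -> Tensor:
    counts = np.bincount(seg_ids, minlength=num_segments).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    acc = np.zeros((num_segments,) + t.data.shape[1:])
    np.add.at(acc, seg_ids, t.data)
    out = Tensor(acc / counts.reshape((-1,) + (1,) * (t.data.ndim - 1)), _prev=(t,))

    def bw(g):
        if t.requires_grad:
            t._accum((g / counts.reshape((-1,) + (1,) * (g.ndim - 1)))[seg_ids])

    out._backward = bw
    return out


def segment_max(t: Tensor, seg_ids: np.ndarray, num_segments: int) -> Tensor:
    n = t.data.shape[0]
    data2 = t.data.reshape(n, -1)
    c = data2.shape[1]
    acc = np.full((num_segments, c), -np.inf)
    np.maximum.at(acc, seg_ids, data2)
    # gradient goes to the lowest-index row attaining each segment/channel max
    winner = np.full((num_segments, c), n, dtype=np.int64)
    is_max = data2 == acc[seg_ids]
    cand = np.where(is_max, np.arange(n)[:, None], n)
    np.minimum.at(winner, seg_ids, cand)
    out = Tensor(acc.reshape((num_segments,) + t.data.shape[1:]), _prev=(t,))

    def bw(g):
        if t.requires_grad:
            full = np.zeros((n, c))
            w = winner.ravel()
            cols = np.tile(np.arange(c), num_segments)
            ok = w < n  # empty segments route no gradient
            np.add.at(full, (w[ok], cols[ok]), g.reshape(num_segments, -1).ravel()[ok])
            t._accum(full.reshape(t.data.shape))

    out._backward = bw
    return out
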