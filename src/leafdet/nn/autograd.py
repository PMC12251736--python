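"""A small reverse-mode automatic-differentiation engine on numpy arrays.

This powers every network block and the training loop in the package.  It
follows the classic tape design: each operation produces a new
:class:`Tensor` holding the forward value, references to its parents and a
closure that maps the output gradient to parent gradients.
:meth:`Tensor.backward` runs the closures in reverse topological order.

Only the operations the detector actually needs are implemented:
broadcasted arithmetic, the activations (sigmoid / SiLU), arctan (for the
CIoU aspect term), reductions, shape manipulation and fancy indexing, plus
the convolution / pooling / upsampling primitives in
:mod:`leafdet.nn.functional`.  Everything is float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "no_grad"]


class _NoGrad:
    """Context manager disabling graph construction (used by the assigner)."""

    _active = False

    def __enter__(self):
        self._prev = _NoGrad._active
        _NoGrad._active = True
        return self

    def __exit__(self, *exc):
        _NoGrad._active = self._prev
        return False


def no_grad() -> _NoGrad:
    return _NoGrad()


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    """Overflow-free logistic function."""
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    """A numpy array plus gradient bookkeeping."""

    _is_tensor = True  # duck-typing marker used by leafdet.boxes
    __array_ufunc__ = None  # make numpy defer to our reflected operators
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad) and not _NoGrad._active
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if not _NoGrad._active and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic properties ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def __len__(self):
        return len(self.data)

    # -- gradient accumulation ----------------------------------------------

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        """Back-propagate from this tensor (default seed: ones)."""
        topo, visited = [], set()

        def visit(t: "Tensor"):
            if id(t) in visited or not t.requires_grad:
                return
            visited.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.ones_like(self.data) if grad is None else np.asarray(grad, np.float32))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        o = Tensor._wrap(other)
        data = self.data + o.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g, o.data.shape))

        return Tensor._make(data, (self, o), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        o = Tensor._wrap(other)
        data = self.data * o.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * self.data, o.data.shape))

        return Tensor._make(data, (self, o), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = Tensor._wrap(other)
        data = self.data / o.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g * self.data / (o.data * o.data), o.data.shape))

        return Tensor._make(data, (self, o), bw)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)
        data = self.data**p

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(data, (self,), bw)

    # -- elementwise functions ----------------------------------------------

    def exp(self):
        data = np.exp(self.data)

        def bw(g):
            self._accum(g * data)

        return Tensor._make(data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        data = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / (data + 1e-12))

        return Tensor._make(data, (self,), bw)

    def atan(self):
        def bw(g):
            self._accum(g / (1.0 + self.data * self.data))

        return Tensor._make(np.arctan(self.data), (self,), bw)

    def sigmoid(self):
        data = _stable_sigmoid(self.data)

        def bw(g):
            self._accum(g * data * (1.0 - data))

        return Tensor._make(data, (self,), bw)

    def silu(self):
        s = _stable_sigmoid(self.data)
        data = self.data * s

        def bw(g):
            self._accum(g * (s * (1.0 + self.data * (1.0 - s))))

        return Tensor._make(data, (self,), bw)

    def maximum(self, other):
        o = Tensor._wrap(other)
        data = np.maximum(self.data, o.data)
        mask = self.data >= o.data  # ties route the gradient to self

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * mask, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * (~mask), o.data.shape))

        return Tensor._make(data, (self, o), bw)

    def minimum(self, other):
        o = Tensor._wrap(other)
        data = np.minimum(self.data, o.data)
        mask = self.data <= o.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * mask, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * (~mask), o.data.shape))

        return Tensor._make(data, (self, o), bw)

    def clip(self, lo: float, hi: float):
        data = np.clip(self.data, lo, hi)
        mask = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(data, (self,), bw)

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * data).sum(axis=axis, keepdims=True)
            self._accum(data * (g - dot))

        return Tensor._make(data, (self,), bw)

    # -- shape manipulation --------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, key):
        data = self.data[key]

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        return Tensor._make(data, (self,), bw)


def concat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` (differentiable)."""
    ts = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(data, ts, bw)


def stack(tensors, axis: int = 0) -> Tensor:
    """Stack tensors along a new ``axis`` (differentiable)."""
    ts = [Tensor._wrap(t) for t in tensors]
    data = np.stack([t.data for t in ts], axis=axis)

    def bw(g):
        parts = np.moveaxis(g, axis, 0)
        for t, p in zip(ts, parts):
            if t.requires_grad:
                t._accum(p)

    return Tensor._make(data, ts, bw)
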