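"""A minimal reverse-mode automatic-differentiation engine on NumPy arrays.

Implements exactly the operations needed by the translation networks:
elementwise arithmetic, logs/exponentials, activations, reductions with
axes, reshapes, concatenation, 2-D convolution (im2col), average pooling
and nearest-neighbour upsampling.  All data is float64 NCHW; gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward` over a
topologically sorted graph.

The engine is deliberately small: no broadcasting tricks beyond NumPy's
own, no in-place ops, no views that alias ``data``.  Every op is checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _sum_to(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` (produced under broadcasting) back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        track = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=track)
        if track:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray):
        if self.requires_grad:
            self.grad = g if self.grad is None else self.grad + g

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
        return Tensor(self.data.copy(), requires_grad=False)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node)

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return power(self, p)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(out):
        a._accum(_sum_to(out.grad, a.data.shape))
        b._accum(_sum_to(out.grad, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(out):
        a._accum(_sum_to(out.grad * b.data, a.data.shape))
        b._accum(_sum_to(out.grad * a.data, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(out):
        a._accum(_sum_to(out.grad / b.data, a.data.shape))
        b._accum(_sum_to(-out.grad * a.data / (b.data ** 2), b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** p

    def backward(out):
        a._accum(out.grad * p * a.data ** (p - 1))

    return Tensor._make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward(out):
        a._accum(out.grad / a.data)

    return Tensor._make(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(out):
        a._accum(out.grad * out.data)

    return Tensor._make(out_data, (a,), backward)


def absolute(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.abs(a.data)

    def backward(out):
        a._accum(out.grad * np.sign(a.data))

    return Tensor._make(out_data, (a,), backward)


def clamp(a, lo: float, hi: float) -> Tensor:
    """Clamp values to [lo, hi]; gradient is zero outside the interval."""
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(out):
        a._accum(out.grad * mask)

    return Tensor._make(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # numerically stable two-branch logistic
    x = a.data
    out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

    def backward(out):
        a._accum(out.grad * out.data * (1.0 - out.data))

    return Tensor._make(out_data, (a,), backward)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def backward(out):
        a._accum(out.grad * (1.0 - out.data ** 2))

    return Tensor._make(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.maximum(a.data, 0.0)

    def backward(out):
        a._accum(out.grad * (a.data > 0))

    return Tensor._make(out_data, (a,), backward)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    out_data = np.where(a.data > 0, a.data, slope * a.data)

    def backward(out):
        a._accum(out.grad * np.where(a.data > 0, 1.0, slope))

    return Tensor._make(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(out):
        g = out.grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape).copy())

    return Tensor._make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)])
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(out):
        a._accum(out.grad.reshape(a.data.shape))

    return Tensor._make(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(out):
        a._accum(out.grad.transpose(inv))

    return Tensor._make(out_data, (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(out):
        pieces = np.split(out.grad, splits, axis=axis)
        for t, g in zip(tensors, pieces):
            t._accum(g)

    return Tensor._make(out_data, tuple(tensors), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(out):
        a._accum(_sum_to(out.grad @ np.swapaxes(b.data, -1, -2), a.data.shape))
        b._accum(_sum_to(np.swapaxes(a.data, -1, -2) @ out.grad, b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# spatial ops (NCHW)
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    """(N,C,Hp,Wp) -> (N, Ho*Wo, C*kh*kw) patch matrix."""
    from numpy.lib.stride_tricks import sliding_window_view

    v = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, ho, wo = v.shape[:4]
    cols = v.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation.  x:(N,Cin,H,W)  w:(Cout,Cin,kh,kw)  b:(Cout,)."""
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    n, cin, h, wd = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols, ho, wo = _im2col(xp, kh, kw, stride)
    wmat = w.data.reshape(cout, -1)
    out_data = cols @ wmat.T  # (N, Ho*Wo, Cout)
    if b is not None:
        out_data = out_data + b.data
    out_data = out_data.transpose(0, 2, 1).reshape(n, cout, ho, wo)

    parents = (x, w) if b is None else (x, w, b)

    def backward(out):
        g = out.grad.reshape(n, cout, ho * wo).transpose(0, 2, 1)  # (N,L,Cout)
        if b is not None:
            b._accum(g.sum(axis=(0, 1)))
        w._accum(np.einsum("nlo,nlk->ok", g, cols).reshape(w.data.shape))
        if x.requires_grad:
            dcols = g @ wmat  # (N, L, C*kh*kw)
            dcols = dcols.reshape(n, ho, wo, cin, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * ho:stride,
                        j:j + stride * wo:stride] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._make(out_data, parents, backward)


def avg_pool2d(x, k: int) -> Tensor:
    """Non-overlapping k×k mean pooling; H, W must be divisible by k."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"avg_pool2d: {h}x{w} not divisible by {k}")
    out_data = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(out):
        g = out.grad / (k * k)
        g = np.repeat(np.repeat(g, k, axis=2), k, axis=3)
        x._accum(g)

    return Tensor._make(out_data, (x,), backward)


def upsample_nearest(x, k: int) -> Tensor:
    x = as_tensor(x)
    out_data = np.repeat(np.repeat(x.data, k, axis=2), k, axis=3)
    n, c, h, w = x.data.shape

    def backward(out):
        g = out.grad.reshape(n, c, h, k, w, k).sum(axis=(3, 5))
        x._accum(g)

    return Tensor._make(out_data, (x,), backward)
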