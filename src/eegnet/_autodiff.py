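"""Minimal reverse-mode gradient engine over numpy arrays.

The fine-tuning stage of the network needs gradients through convolutions,
rectified squared-response activations, max-pooling, layer normalisation and
attention. This module provides a small tape-based autodiff: a :class:`Tensor`
wraps an ndarray and records a backward closure per operation; ``backward()``
runs reverse topological order. Every primitive's gradient is verified against
central finite differences in the test suite.

All public ops *dispatch*: given plain ndarrays they compute with numpy and
return ndarrays; given at least one Tensor they build the graph. This lets the
forward passes of the network be written once and reused for inference
(numpy) and training (autodiff).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # defer mixed ndarray/Tensor arithmetic to the Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph mechanics -----------------------------------------------
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(other, power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, *shape)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)


def _is_tensor(*xs):
    return any(isinstance(x, Tensor) for x in xs)


def asdata(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _astensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / reduction primitives
# ---------------------------------------------------------------------------

def add(a, b):
    if not _is_tensor(a, b):
        return asdata(a) + asdata(b)
    a, b = _astensor(a), _astensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def mul(a, b):
    if not _is_tensor(a, b):
        return asdata(a) * asdata(b)
    a, b = _astensor(a), _astensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward
    return out


def power(a, p):
    if not isinstance(p, (int, float)):
        raise TypeError("power exponent must be a scalar")
    if not _is_tensor(a):
        return asdata(a) ** p
    a = _astensor(a)
    out = Tensor(a.data ** p, parents=(a,))

    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1))

    out._backward = backward
    return out


def exp(a):
    if not _is_tensor(a):
        return np.exp(asdata(a))
    a = _astensor(a)
    out = Tensor(np.exp(a.data), parents=(a,))
    out._backward = lambda g: a._accumulate(g * out.data)
    return out


def log(a):
    if not _is_tensor(a):
        return np.log(asdata(a))
    a = _astensor(a)
    out = Tensor(np.log(a.data), parents=(a,))
    out._backward = lambda g: a._accumulate(g / a.data)
    return out


def sqrt(a):
    return power(a, 0.5)


def relu(a):
    if not _is_tensor(a):
        d = asdata(a)
        return np.maximum(d, 0.0)
    a = _astensor(a)
    out = Tensor(np.maximum(a.data, 0.0), parents=(a,))
    out._backward = lambda g: a._accumulate(g * (a.data > 0))
    return out


def sigmoid(a):
    if not _is_tensor(a):
        return expit(asdata(a))
    a = _astensor(a)
    y = expit(a.data)
    out = Tensor(y, parents=(a,))
    out._backward = lambda g: a._accumulate(g * y * (1.0 - y))
    return out


def sum_(a, axis=None, keepdims=False):
    if not _is_tensor(a):
        return asdata(a).sum(axis=axis, keepdims=keepdims)
    a = _astensor(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    out._backward = backward
    return out


def mean_(a, axis=None, keepdims=False):
    d = asdata(a)
    if axis is None:
        n = d.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([d.shape[ax] for ax in axes]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, *shape):
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    if not _is_tensor(a):
        return asdata(a).reshape(shape)
    a = _astensor(a)
    out = Tensor(a.data.reshape(shape), parents=(a,))
    out._backward = lambda g: a._accumulate(g.reshape(a.data.shape))
    return out


def transpose(a, axes):
    if not _is_tensor(a):
        return asdata(a).transpose(axes)
    a = _astensor(a)
    out = Tensor(a.data.transpose(axes), parents=(a,))
    inv = np.argsort(axes)
    out._backward = lambda g: a._accumulate(g.transpose(inv))
    return out


def matmul(a, b):
    if not _is_tensor(a, b):
        return asdata(a) @ asdata(b)
    a, b = _astensor(a), _astensor(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def backward(g):
        ad_, bd = a.data, b.data
        # promote 1-D operands to 2-D for the gradient algebra
        a2 = ad_[None, :] if ad_.ndim == 1 else ad_
        b2 = bd[:, None] if bd.ndim == 1 else bd
        g2 = g
        if ad_.ndim == 1:
            g2 = g2[..., None, :]
        if bd.ndim == 1:
            g2 = g2[..., :, None]
        ga = g2 @ np.swapaxes(b2, -1, -2)
        gb = np.swapaxes(a2, -1, -2) @ g2
        if ad_.ndim == 1:
            ga = ga.reshape(ga.shape[:-2] + (ad_.shape[0],))
        if bd.ndim == 1:
            gb = gb.reshape(gb.shape[:-2] + (bd.shape[0],))
        a._accumulate(_unbroadcast(ga, ad_.shape))
        b._accumulate(_unbroadcast(gb, bd.shape))

    out._backward = backward
    return out


def softmax(a, axis=-1):
    """Numerically stable softmax (primitive, with its own jacobian rule)."""
    if not _is_tensor(a):
        d = asdata(a)
        m = d.max(axis=axis, keepdims=True)
        e = np.exp(d - m)
        return e / e.sum(axis=axis, keepdims=True)
    a = _astensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(a,))

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        a._accumulate(y * (g - dot))

    out._backward = backward
    return out


def layer_norm(x, gamma, beta, eps=1e-5):
    """Normalise over the last axis, then scale and shift (composite op)."""
    mu = mean_(x, axis=-1, keepdims=True)
    xc = add(x, mul(mu, -1.0))
    var = mean_(mul(xc, xc), axis=-1, keepdims=True)
    xhat = mul(xc, power(add(var, eps), -0.5))
    return add(mul(xhat, gamma), beta)


# ---------------------------------------------------------------------------
# convolution / pooling primitives
# ---------------------------------------------------------------------------

def _pad_hw(x, p):
    if p == 0:
        return x
    pads = [(0, 0)] * (x.ndim - 2) + [(p, p), (p, p)]
    return np.pad(x, pads)


def _conv2d_data(x, w, padding):
    """Valid-mode multichannel cross-correlation.

    x: [N, C, H, W]; w: [K, C, kh, kw] -> [N, K, H-kh+1+2p, W-kw+1+2p]
    """
    xp = _pad_hw(x, padding)
    kh, kw = w.shape[-2:]
    win = sliding_window_view(xp, (kh, kw), axis=(-2, -1))  # N,C,H',W',kh,kw
    return np.einsum("nchwij,kcij->nkhw", win, w, optimize=True)


def conv2d(x, w, padding=0):
    """Cross-correlate a [N,C,H,W] batch with [K,C,kh,kw] kernels.

    Symmetric zero padding ``padding`` on both spatial axes; valid mode
    otherwise (output H' = H + 2p - kh + 1).
    """
    if not _is_tensor(x, w):
        return _conv2d_data(asdata(x), asdata(w), padding)
    x, w = _astensor(x), _astensor(w)
    out = Tensor(_conv2d_data(x.data, w.data, padding), parents=(x, w))
    kh, kw = w.data.shape[-2:]
    p = padding

    def backward(g):
        xp = _pad_hw(x.data, p)
        win = sliding_window_view(xp, (kh, kw), axis=(-2, -1))
        gw = np.einsum("nchwij,nkhw->kcij", win, g, optimize=True)
        w._accumulate(gw)
        # grad wrt x: full correlation of g with kernels flipped in space,
        # contracted over K; equals conv_transpose.
        gp = _pad_hw(g, max(kh, kw) - 1) if kh == kw else None
        if gp is None:  # pragma: no cover - square kernels only in practice
            raise NotImplementedError("non-square kernels")
        gwin = sliding_window_view(gp, (kh, kw), axis=(-2, -1))
        wflip = w.data[:, :, ::-1, ::-1]
        gx_full = np.einsum("nkhwij,kcij->nchw", gwin, wflip, optimize=True)
        # crop padding back off
        if p:
            gx_full = gx_full[:, :, p:-p, p:-p]
        x._accumulate(gx_full)

    out._backward = backward
    return out


def conv_transpose2d(h, w, padding=0):
    """Adjoint of :func:`conv2d`: project hidden maps back to visible space.

    h: [N, K, Hh, Ww]; w: [K, C, kh, kw] -> [N, C, Hv, Wv]. Used for the
    top-down term of the visible conditional.
    """
    hd, wd = asdata(h), asdata(w)
    kh, kw = wd.shape[-2:]
    hp = _pad_hw(hd, kh - 1)
    win = sliding_window_view(hp, (kh, kw), axis=(-2, -1))
    wflip = wd[:, :, ::-1, ::-1]
    out = np.einsum("nkhwij,kcij->nchw", win, wflip, optimize=True)
    if padding:
        out = out[:, :, padding:-padding, padding:-padding]
    return out


def maxpool2d(x, pool):
    """Non-overlapping block max over the trailing two axes.

    Floor division: trailing rows/columns that do not fill a block are
    discarded (they receive zero gradient).
    """
    if pool == 1:
        return x
    d = asdata(x)
    n, k, h, w = d.shape
    hb, wb = h // pool, w // pool
    crop = d[:, :, : hb * pool, : wb * pool]
    blocks = crop.reshape(n, k, hb, pool, wb, pool).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(n, k, hb, wb, pool * pool)
    idx = flat.argmax(axis=-1)
    pooled = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    if not _is_tensor(x):
        return pooled
    x = _astensor(x)
    out = Tensor(pooled, parents=(x,))

    def backward(g):
        gflat = np.zeros((n, k, hb, wb, pool * pool))
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gcrop = (
            gflat.reshape(n, k, hb, wb, pool, pool)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, k, hb * pool, wb * pool)
        )
        gx = np.zeros_like(x.data)
        gx[:, :, : hb * pool, : wb * pool] = gcrop
        x._accumulate(gx)

    out._backward = backward
    return out
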