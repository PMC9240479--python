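"""Tape-based reverse-mode automatic differentiation over numpy arrays.

A compact dynamic-graph engine in the micrograd style: each operation
returns a :class:`Tensor` holding its value, its parents, and a closure
that accumulates gradients into the parents. ``Tensor.backward`` runs a
topological sort and replays the closures in reverse.

All arithmetic is float32. Convolution is lowered to matrix products via
``im2col`` (a loop over the kernel offsets, each offset a strided slice),
so the heavy lifting lands in BLAS. Transposed convolution is restricted
to kernel_size == stride (the non-overlapping case used for 2x2 stride-2
upsampling), where the forward pass is a single ``einsum`` scatter.
"""

from __future__ import annotations

import contextlib

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad=False, _prev=(), name=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32, copy=True).reshape(self.data.shape)
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen = set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
        # break the closure reference cycles (node -> closure -> node) so
        # large intermediate buffers are freed by refcount, not gc passes
        for t in topo:
            t._backward = None
            t._prev = ()

    def zero_grad(self):
        self.grad = None


def _make(data, parents, backward):
    """Build a graph node; collapses to a bare Tensor under no_grad."""
    req = _grad_enabled and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req, _prev=tuple(parents) if req else ())
    if req:
        out._backward = backward(out)
    return out


def astensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------- basic ops

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    data = a.data + b.data

    def bw(out):
        def run():
            a._accum(_unbroadcast(out.grad, a.data.shape))
            b._accum(_unbroadcast(out.grad, b.data.shape))
        return run

    return _make(data, (a, b), bw)


def _unbroadcast(g, shape):
    """Sum gradient g down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = astensor(a), astensor(b)
    data = a.data * b.data

    def bw(out):
        def run():
            a._accum(_unbroadcast(out.grad * b.data, a.data.shape))
            b._accum(_unbroadcast(out.grad * a.data, b.data.shape))
        return run

    return _make(data, (a, b), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def bw(out):
        def run():
            a._accum(out.grad @ b.data.T)
            b._accum(a.data.T @ out.grad)
        return run

    return _make(data, (a, b), bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    data = np.where(mask, x.data, 0.0)

    def bw(out):
        def run():
            x._accum(out.grad * mask)
        return run

    return _make(data, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    xd = x.data
    data = np.where(xd >= 0, 1.0 / (1.0 + np.exp(-np.abs(xd))),
                    np.exp(-np.abs(xd)) / (1.0 + np.exp(-np.abs(xd)))).astype(np.float32)

    def bw(out):
        def run():
            x._accum(out.grad * data * (1.0 - data))
        return run

    return _make(data, (x,), bw)


def mean(x: Tensor) -> Tensor:
    data = np.asarray(x.data.mean(), dtype=np.float32)

    def bw(out):
        def run():
            x._accum(np.full_like(x.data, out.grad / x.data.size))
        return run

    return _make(data, (x,), bw)


def concat(tensors, axis=1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def bw(out):
        def run():
            splits = np.cumsum(sizes)[:-1]
            for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
                t._accum(g)
        return run

    return _make(data, tuple(tensors), bw)


# --------------------------------------------------------------- conv ops

def _im2col(x, kh, kw, stride, pad):
    """(N,C,H,W) -> (N, C*kh*kw, oh*ow) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
    return cols.reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(cols, x_shape, kh, kw, stride, pad):
    """Scatter-add inverse of _im2col."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, oh, ow)
    xg = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xg[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += cols[:, :, i, j]
    if pad:
        xg = xg[:, :, pad:hp - pad, pad:wp - pad]
    return xg


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, pad=0) -> Tensor:
    """2D cross-correlation; w is (F, C, kh, kw), b is (F,) or None."""
    f, c, kh, kw = w.data.shape
    n = x.data.shape[0]
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    wm = w.data.reshape(f, -1)
    out_d = np.matmul(wm, cols).reshape(n, f, oh, ow)
    if b is not None:
        out_d += b.data.reshape(1, f, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bw(out):
        def run():
            g = np.ascontiguousarray(out.grad).reshape(n, f, oh * ow)
            if w.requires_grad:
                dw = np.matmul(g, cols.transpose(0, 2, 1)).sum(axis=0)
                w._accum(dw.reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2)))
            if x.requires_grad:
                dcols = np.matmul(wm.T, g)
                x._accum(_col2im(dcols, x.data.shape, kh, kw, stride, pad))
        return run

    return _make(out_d, parents, bw)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=2) -> Tensor:
    """Non-overlapping transposed convolution: kernel size == stride.

    w is (C_in, F, k, k). Doubles (for stride 2) the spatial size; each
    input pixel paints a disjoint k x k output patch, so forward and
    backward are single einsums.
    """
    c_in, f, k, _ = w.data.shape
    if k != stride:
        raise ValueError("conv_transpose2d supports kernel_size == stride only")
    n, c, h, wd = x.data.shape
    out_d = np.einsum("nchw,cfij->nfhiwj", x.data, w.data, optimize=True)
    out_d = out_d.reshape(n, f, h * k, wd * k)
    if b is not None:
        out_d += b.data.reshape(1, f, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bw(out):
        def run():
            g = out.grad.reshape(n, f, h, k, wd, k)
            if w.requires_grad:
                w._accum(np.einsum("nchw,nfhiwj->cfij", x.data, g, optimize=True))
            if b is not None and b.requires_grad:
                b._accum(out.grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                x._accum(np.einsum("nfhiwj,cfij->nchw", g, w.data, optimize=True))
        return run

    return _make(out_d, parents, bw)


def maxpool2d(x: Tensor, kernel=2, stride=None, pad=0) -> Tensor:
    stride = stride or kernel
    n, c, h, w = x.data.shape
    xd = x.data
    if pad:
        xd = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                    constant_values=-np.inf)
    hp, wp = xd.shape[2], xd.shape[3]
    oh = (hp - kernel) // stride + 1
    ow = (wp - kernel) // stride + 1
    wins = np.empty((n, c, kernel * kernel, oh, ow), dtype=np.float32)
    idx = 0
    for i in range(kernel):
        for j in range(kernel):
            wins[:, :, idx] = xd[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
            idx += 1
    arg = wins.argmax(axis=2)
    out_d = np.take_along_axis(wins, arg[:, :, None], axis=2)[:, :, 0]

    def bw(out):
        def run():
            dwins = np.zeros_like(wins)
            np.put_along_axis(dwins, arg[:, :, None], out.grad[:, :, None], axis=2)
            xg = np.zeros((n, c, hp, wp), dtype=np.float32)
            idx2 = 0
            for i in range(kernel):
                for j in range(kernel):
                    xg[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += dwins[:, :, idx2]
                    idx2 += 1
            if pad:
                xg = xg[:, :, pad:hp - pad, pad:wp - pad]
            x._accum(xg)
        return run

    return _make(out_d, (x,), bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C): the SE squeeze, z_c = mean over H,W."""
    n, c, h, w = x.data.shape
    data = x.data.mean(axis=(2, 3))

    def bw(out):
        def run():
            x._accum(np.broadcast_to(out.grad[:, :, None, None] / (h * w),
                                     x.data.shape).astype(np.float32))
        return run

    return _make(data, (x,), bw)


def channel_scale(x: Tensor, s: Tensor) -> Tensor:
    """(N,C,H,W) scaled per-channel by s of shape (N,C): the SE rescale."""
    data = x.data * s.data[:, :, None, None]

    def bw(out):
        def run():
            if x.requires_grad:
                x._accum(out.grad * s.data[:, :, None, None])
            if s.requires_grad:
                s._accum((out.grad * x.data).sum(axis=(2, 3)))
        return run

    return _make(data, (x, s), bw)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean, running_var,
                training: bool, momentum=0.1, eps=1e-5) -> Tensor:
    """Batch normalization over (N,H,W) per channel; updates running stats in place."""
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bw(out):
        def run():
            g = out.grad
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                gxh = g * gamma.data[None, :, None, None]
                if training:
                    sum_gxh = gxh.sum(axis=(0, 2, 3))
                    sum_gxh_xhat = (gxh * xhat).sum(axis=(0, 2, 3))
                    dx = (inv[None, :, None, None] / m) * (
                        m * gxh
                        - sum_gxh[None, :, None, None]
                        - xhat * sum_gxh_xhat[None, :, None, None]
                    )
                else:
                    dx = gxh * inv[None, :, None, None]
                x._accum(dx.astype(np.float32))
        return run

    return _make(data, (x, gamma, beta), bw)


def softmax_cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy. logits (N,K,H,W), target (N,H,W) int."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n, k, h, w = p.shape
    t = np.asarray(target)
    picked = np.take_along_axis(p, t[:, None], axis=1)[:, 0]
    npix = n * h * w
    data = np.asarray(-np.log(np.maximum(picked, 1e-12)).sum() / npix, dtype=np.float32)

    def bw(out):
        def run():
            onehot = np.zeros_like(p)
            np.put_along_axis(onehot, t[:, None], 1.0, axis=1)
            logits._accum(out.grad * (p - onehot) / npix)
        return run

    return _make(data, (logits,), bw)
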