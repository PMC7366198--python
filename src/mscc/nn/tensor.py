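"""Reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  Only the operations needed by the segmentation
networks are implemented (2-D convolution and its transpose, batch
normalisation, pooling, dense layers, the usual pointwise nonlinearities and
the two cross-entropy losses).  Arrays keep whatever float dtype they are
given, so gradient-check tests can run the whole graph in float64 while
training runs in float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """A node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # free intermediate gradients; leaves keep theirs
                node._backward = None


def _make(data, parents, backward):
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = False
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _needs(t: Tensor) -> bool:
    return t.requires_grad or bool(t._parents)


# -- elementwise and shape operations -------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if _needs(a):
            a._accumulate(_unbroadcast(g, a.data.shape))
        if _needs(b):
            b._accumulate(_unbroadcast(g, b.data.shape))
    return _make(a.data + b.data, (a, b), backward)


def _unbroadcast(g, shape):
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if _needs(x):
            x._accumulate(g * mask)
    return _make(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def backward(g):
        if _needs(x):
            x._accumulate(g * s * (1.0 - s))
    return _make(s, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    orig = x.data.shape

    def backward(g):
        if _needs(x):
            x._accumulate(g.reshape(orig))
    return _make(x.data.reshape(shape), (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if _needs(t):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])
    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x: (N, D), w: (D, K), b: (K,)."""
    def backward(g):
        if _needs(x):
            x._accumulate(g @ w.data.T)
        if _needs(w):
            w._accumulate(x.data.T @ g)
        if _needs(b):
            b._accumulate(g.sum(axis=0))
    return _make(x.data @ w.data + b.data, (x, w, b), backward)


# -- convolution -----------------------------------------------------------

def _pad_hw(x, pt, pb, pl, pr):
    if pt == pb == pl == pr == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'same'-padded stride-1 correlation.

    x: (N, C, H, W); w: (F, C, kh, kw); b: (F,).  Even kernel sizes are not
    needed by the networks and are rejected.
    """
    kh, kw = w.data.shape[2], w.data.shape[3]
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d expects odd kernel dimensions")
    ph, pw = kh // 2, kw // 2
    xp = _pad_hw(x.data, ph, ph, pw, pw)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N,C,H,W,kh,kw)
    out = np.tensordot(win, w.data, axes=([1, 4, 5], [1, 2, 3]))
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2)) + b.data[None, :, None, None]

    def backward(g):
        if _needs(b):
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if _needs(w):
            xp_b = _pad_hw(x.data, ph, ph, pw, pw)
            win_b = sliding_window_view(xp_b, (kh, kw), axis=(2, 3))
            dw = np.tensordot(g, win_b, axes=([0, 2, 3], [0, 2, 3]))
            w._accumulate(dw)
        if _needs(x):
            gp = _pad_hw(g, ph, ph, pw, pw)
            gw = sliding_window_view(gp, (kh, kw), axis=(2, 3))  # (N,F,H,W,kh,kw)
            wf = w.data[:, :, ::-1, ::-1]  # (F,C,kh,kw) flipped
            dx = np.tensordot(gw, wf, axes=([1, 4, 5], [0, 2, 3]))
            x._accumulate(np.ascontiguousarray(dx.transpose(0, 3, 1, 2)))
    return _make(out, (x, w, b), backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2-kernel, stride-2 transposed convolution (exact 2x upsampling).

    x: (N, C, H, W); w: (C, F, 2, 2); b: (F,); output (N, F, 2H, 2W).
    """
    n, c, h, wd = x.data.shape
    f = w.data.shape[1]
    t = np.tensordot(x.data, w.data, axes=([1], [0]))  # (n,h,w,f,2,2)
    out = (t.transpose(0, 3, 1, 4, 2, 5).reshape(n, f, 2 * h, 2 * wd)
           + b.data[None, :, None, None])

    def backward(g):
        gt = g.reshape(n, f, h, 2, wd, 2)
        if _needs(b):
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if _needs(w):
            # contract (n, h, w) between x and the block-structured gradient
            dw = np.tensordot(x.data, gt, axes=([0, 2, 3], [0, 2, 4]))
            w._accumulate(dw)  # (c, f, 2, 2)
        if _needs(x):
            dx = np.tensordot(gt, w.data, axes=([1, 3, 5], [1, 2, 3]))
            x._accumulate(np.ascontiguousarray(dx.transpose(0, 3, 1, 2)))
    return _make(out, (x, w, b), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 needs even spatial dimensions")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]

    def backward(g):
        if _needs(x):
            counts = mask.sum(axis=(3, 5), keepdims=True)
            gr = (g[:, :, :, None, :, None] * mask) / counts
            x._accumulate(gr.reshape(n, c, h, w))
    return _make(out, (x,), backward)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean,
                 running_var, training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (N, H, W).

    ``running_mean``/``running_var`` are plain arrays updated in place during
    training and used verbatim in evaluation mode.
    """
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    out = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]

    def backward(g):
        if _needs(gamma):
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if _needs(beta):
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if _needs(x):
            gi = g * gamma.data[None, :, None, None]
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                s1 = gi.sum(axis=(0, 2, 3))
                s2 = (gi * xhat).sum(axis=(0, 2, 3))
                dx = (gi - s1[None, :, None, None] / m
                      - xhat * s2[None, :, None, None] / m) * inv[None, :, None, None]
            else:
                dx = gi * inv[None, :, None, None]
            x._accumulate(dx)
    return _make(out, (x, gamma, beta), backward)


# -- losses ----------------------------------------------------------------

def bce_with_logits(logits: Tensor, targets) -> Tensor:
    """Mean binary cross-entropy, numerically stable in the logits."""
    t = np.asarray(targets, dtype=logits.data.dtype)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    def backward(g):
        if _needs(logits):
            logits._accumulate(g * (p - t) / z.size)
    return _make(np.array(loss.mean(), dtype=z.dtype), (logits,), backward)


def softmax_cross_entropy(logits: Tensor, labels) -> Tensor:
    """Mean categorical cross-entropy; logits (N, K), integer labels (N,)."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    idx = (np.arange(n), np.asarray(labels))
    loss = -np.log(np.clip(p[idx], 1e-30, None)).mean()

    def backward(g):
        if _needs(logits):
            dz = p.copy()
            dz[idx] -= 1.0
            logits._accumulate(g * dz / n)
    return _make(np.array(loss, dtype=z.dtype), (logits,), backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    zmax = x.data.max(axis=axis, keepdims=True)
    ez = np.exp(x.data - zmax)
    s = ez / ez.sum(axis=axis, keepdims=True)

    def backward(g):
        if _needs(x):
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate(s * (g - dot))
    return _make(s, (x,), backward)
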