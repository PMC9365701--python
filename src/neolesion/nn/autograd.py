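"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the 2D segmentation networks need:
stride-1 "same" convolutions, 2x stride-2 transpose convolutions, batch
normalization, 2x2 max/average pooling, nearest upsampling, channel
concatenation, and the elementwise/reduction ops used by the dice+focal
loss. Every op provides an analytic vector-Jacobian product; the test
suite checks each against central differences.

Tensors are thin wrappers around ``numpy.ndarray``. Gradients are
accumulated by a topological-order sweep from the output.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "constant", "add", "mul", "neg", "clip", "log", "power",
    "reduce_sum", "reduce_mean", "relu", "sigmoid", "conv2d",
    "conv_transpose2d", "batch_norm2d", "max_pool2d", "avg_pool2d",
    "upsample_nearest2d", "concat_channels",
]


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._vjp = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def backward(self, grad=None):
        """Accumulate gradients of ``self`` w.r.t. every reachable leaf."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                topo.append(node)
                continue
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            parent_grads = node._vjp(node.grad)
            for parent, g in zip(node._parents, parent_grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(parent.data.dtype, copy=False)
                else:
                    parent.grad = parent.grad + g

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _node(data, parents, vjp) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._vjp = vjp
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------- elementwise

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data + b.data

    def vjp(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _node(out, (a, b), vjp)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data * b.data

    def vjp(g):
        return (_unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape))

    return _node(out, (a, b), vjp)


def neg(a) -> Tensor:
    a = _as_tensor(a)
    return _node(-a.data, (a,), lambda g: (-g,))


def clip(a, lo: float, hi: float) -> Tensor:
    a = _as_tensor(a)
    out = np.clip(a.data, lo, hi)
    inside = (a.data > lo) & (a.data < hi)

    def vjp(g):
        return (g * inside,)

    return _node(out, (a,), vjp)


def log(a) -> Tensor:
    a = _as_tensor(a)
    out = np.log(a.data)

    def vjp(g):
        return (g / a.data,)

    return _node(out, (a,), vjp)


def power(a, p: float) -> Tensor:
    """Elementwise ``a ** p`` for a scalar exponent ``p``."""
    a = _as_tensor(a)
    out = a.data ** p

    def vjp(g):
        return (g * p * a.data ** (p - 1.0),)

    return _node(out, (a,), vjp)


def reduce_sum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        g = np.asarray(g)
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        if not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, ax)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    return _node(out, (a,), vjp)


def reduce_mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in ax]))
    s = reduce_sum(a, axis=axis, keepdims=keepdims)
    return mul(s, 1.0 / n)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    out = np.maximum(a.data, 0)
    mask = a.data > 0

    def vjp(g):
        return (g * mask,)

    return _node(out, (a,), vjp)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    # numerically stable logistic
    out = np.empty_like(a.data)
    pos = a.data >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    e = np.exp(a.data[~pos])
    out[~pos] = e / (1.0 + e)

    def vjp(g):
        return (g * out * (1.0 - out),)

    return _node(out, (a,), vjp)


# ---------------------------------------------------------------- convolution

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*k*k) patch matrix for stride-1 same conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, k, k, h, w), strides=(s0, s1, s2, s3, s2, s3))
    return np.ascontiguousarray(cols.transpose(0, 4, 5, 1, 2, 3)).reshape(
        n * h * w, c * k * k)


def _col2im(cols: np.ndarray, shape: tuple, k: int, pad: int) -> np.ndarray:
    n, c, h, w = shape
    cols = cols.reshape(n, h, w, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + h, j:j + w] += cols[:, :, i, j]
    if pad:
        return xp[:, :, pad:-pad, pad:-pad]
    return xp


def conv2d(x, weight, bias) -> Tensor:
    """Stride-1 'same' 2D convolution.

    x: (N, Cin, H, W); weight: (Cout, Cin, k, k) with odd k; bias: (Cout,).
    """
    x, weight, bias = _as_tensor(x), _as_tensor(weight), _as_tensor(bias)
    n, cin, h, w = x.data.shape
    cout, _, k, _ = weight.data.shape
    pad = k // 2
    cols = _im2col(x.data, k, pad)
    wmat = weight.data.reshape(cout, cin * k * k)
    out = cols @ wmat.T + bias.data
    out = out.reshape(n, h, w, cout).transpose(0, 3, 1, 2)

    def vjp(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(n * h * w, cout)
        dw = (g2.T @ cols).reshape(weight.data.shape)
        db = g2.sum(axis=0)
        dcols = g2 @ wmat
        dx = _col2im(dcols, x.data.shape, k, pad)
        return dx, dw, db

    return _node(out, (x, weight, bias), vjp)


def conv_transpose2d(x, weight, bias) -> Tensor:
    """2x2 stride-2 transpose convolution (exact 2x upsampling).

    x: (N, Cin, H, W); weight: (Cin, Cout, 2, 2); bias: (Cout,).
    Output: (N, Cout, 2H, 2W).
    """
    x, weight, bias = _as_tensor(x), _as_tensor(weight), _as_tensor(bias)
    n, cin, h, w = x.data.shape
    _, cout, _, _ = weight.data.shape
    out = np.empty((n, cout, 2 * h, 2 * w), dtype=x.data.dtype)
    for dy in range(2):
        for dx_ in range(2):
            sub = np.tensordot(x.data, weight.data[:, :, dy, dx_],
                               axes=([1], [0]))  # (N,H,W,Cout)
            out[:, :, dy::2, dx_::2] = sub.transpose(0, 3, 1, 2)
    out += bias.data[None, :, None, None]

    def vjp(g):
        dx = np.zeros_like(x.data)
        dw = np.zeros_like(weight.data)
        for dy in range(2):
            for dx_ in range(2):
                gsub = g[:, :, dy::2, dx_::2]  # (N,Cout,H,W)
                dx += np.tensordot(gsub, weight.data[:, :, dy, dx_],
                                   axes=([1], [1])).transpose(0, 3, 1, 2)
                dw[:, :, dy, dx_] = np.tensordot(
                    x.data, gsub, axes=([0, 2, 3], [0, 2, 3]))
        db = g.sum(axis=(0, 2, 3))
        return dx, dw, db

    return _node(out, (x, weight, bias), vjp)


# ------------------------------------------------------------- normalization

def batch_norm2d(x, gamma, beta, running_mean: np.ndarray,
                 running_var: np.ndarray, training: bool,
                 momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    ``running_mean`` / ``running_var`` are plain arrays updated in place
    during training and used directly at inference.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    axes = (0, 2, 3)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mean
        running_var *= (1.0 - momentum)
        running_var += momentum * var
    else:
        mean = running_mean
        var = running_var
    std = np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) / std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def vjp(g):
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        dxhat = g * gamma.data[None, :, None, None]
        if training:
            t1 = m * dxhat
            t2 = dxhat.sum(axis=axes)[None, :, None, None]
            t3 = xhat * (dxhat * xhat).sum(axis=axes)[None, :, None, None]
            dx = (t1 - t2 - t3) / (m * std[None, :, None, None])
        else:
            dx = dxhat / std[None, :, None, None]
        return dx, dgamma, dbeta

    return _node(out, (x, gamma, beta), vjp)


# ------------------------------------------------------------------- pooling

def max_pool2d(x) -> Tensor:
    """2x2 max pooling, stride 2; spatial dims must be even."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2d requires even spatial dimensions")
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(
        0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def vjp(g):
        dwin = np.zeros_like(win)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dx = dwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        return (dx,)

    return _node(out, (x,), vjp)


def avg_pool2d(x) -> Tensor:
    """2x2 average pooling, stride 2."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("avg_pool2d requires even spatial dimensions")
    out = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def vjp(g):
        dx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        return (dx,)

    return _node(out, (x,), vjp)


def upsample_nearest2d(x) -> Tensor:
    """2x nearest-neighbour upsampling."""
    x = _as_tensor(x)
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def vjp(g):
        n, c, h2, w2 = g.shape
        dx = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        return (dx,)

    return _node(out, (x,), vjp)


def concat_channels(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    ca = a.data.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)

    def vjp(g):
        return g[:, :ca], g[:, ca:]

    return _node(out, (a, b), vjp)
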