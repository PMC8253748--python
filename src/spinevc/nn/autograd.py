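"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps a float32 ndarray and
records the operations that produced it; :meth:`Tensor.backward` runs the
chain rule over the recorded graph.  Only the operations needed by the
segmentation and regression networks are provided (stride-1 'same'
convolution with dilation, 2x2 max pooling, nearest-neighbour upsampling,
batch normalisation, channel concatenation, dense layers and elementwise
math).  Data layout for image tensors is NCHW.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "add",
    "mul",
    "concat",
    "relu",
    "sigmoid",
    "conv2d",
    "maxpool2x2",
    "upsample2x",
    "global_avg_pool",
    "linear",
    "batchnorm2d",
    "mse_loss",
    "bce_loss",
]

_DTYPE = np.float32


class Tensor:
    """Node in the computation graph.

    Parameters with ``requires_grad=True`` accumulate gradients in
    ``.grad`` after :meth:`backward`; intermediate nodes receive gradients
    transiently while the backward sweep runs.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: Tensor) -> None:
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free intermediate grads/graph references
        for node in topo:
            if node is not self and not node.requires_grad:
                node.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.astype(_DTYPE, copy=True)
    else:
        t.grad += g


def _node(data, parents, backward) -> Tensor:
    return Tensor(data, _parents=parents, _backward=backward)


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        _accum(a, g)
        _accum(b, g)

    return _node(out_data, (a, b), backward)


def mul(a: Tensor, scalar: float) -> Tensor:
    s = _DTYPE(scalar)
    out_data = a.data * s

    def backward(g):
        _accum(a, g * s)

    return _node(out_data, (a,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _node(out_data, tuple(tensors), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        _accum(x, g * mask)

    return _node(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        _accum(x, g * out_data * (1.0 - out_data))

    return _node(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _conv_raw(x: np.ndarray, w: np.ndarray, dilation: int) -> np.ndarray:
    """Stride-1 'same' cross-correlation, NCHW x (Cout,Cin,kh,kw)."""
    n, c, h, wid = x.shape
    cout, cin, kh, kw = w.shape
    if cin != c:
        raise ValueError(f"channel mismatch: input {c}, kernel {cin}")
    d = int(dilation)
    ekh, ekw = d * (kh - 1) + 1, d * (kw - 1) + 1
    ph, pw = ekh // 2, ekw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (ekh, ekw), axis=(2, 3))
    if d > 1:
        win = win[..., ::d, ::d]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wid, c * kh * kw)
    wmat = w.reshape(cout, c * kh * kw)
    out = cols @ wmat.T
    return out.reshape(n, h, wid, cout).transpose(0, 3, 1, 2), cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Stride-1 'same'-padded 2D convolution (cross-correlation)."""
    out_data, cols = _conv_raw(x.data, w.data, dilation)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)
    n, cout, h, wid = out_data.shape
    cin, kh, kw = w.data.shape[1:]

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * h * wid, cout)
        gw = (gmat.T @ cols).reshape(cout, cin, kh, kw)
        _accum(w, gw)
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))
        # grad wrt input: 'same' correlation of g with the flipped kernel,
        # input/output channels swapped, same dilation (valid for stride 1).
        w_flip = w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        gx, _ = _conv_raw(np.ascontiguousarray(g), np.ascontiguousarray(w_flip), dilation)
        _accum(x, gx)

    return _node(out_data, parents, backward)


# ---------------------------------------------------------------------------
# pooling / resampling
# ---------------------------------------------------------------------------

def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    patches = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = patches.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=_DTYPE)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        _accum(x, gx.reshape(n, c, h, w))

    return _node(out_data, (x,), backward)


def upsample2x(x: Tensor) -> Tensor:
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    n, c, h, w = x.data.shape

    def backward(g):
        _accum(x, g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return _node(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g):
        _accum(x, np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))

    return _node(out_data, (x,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Dense layer: x (N, Fin) @ w.T (Fin, Fout) + b."""
    out_data = x.data @ w.data.T + b.data

    def backward(g):
        _accum(w, g.T @ x.data)
        _accum(b, g.sum(axis=0))
        _accum(x, g @ w.data)

    return _node(out_data, (x, w, b), backward)


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------

def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                mean: np.ndarray, var: np.ndarray, training: bool,
                eps: float = 1e-5) -> Tensor:
    """Channelwise batch norm. ``mean``/``var`` are the statistics to use
    (batch statistics when training, running statistics otherwise)."""
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
    out_data = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)
    n, c, h, w = x.data.shape
    m = n * h * w

    def backward(g):
        _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        _accum(beta, g.sum(axis=(0, 2, 3)))
        ginv = (gamma.data * inv).reshape(1, -1, 1, 1)
        if training:
            gmean = g.mean(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
            gxhat_mean = (g * xhat).mean(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
            _accum(x, ginv * (g - gmean - xhat * gxhat_mean))
        else:
            _accum(x, ginv * g)

    return _node(out_data, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    t = np.asarray(target, dtype=_DTYPE)
    diff = pred.data - t
    out_data = np.array((diff ** 2).mean(), dtype=_DTYPE)

    def backward(g):
        _accum(pred, g * 2.0 * diff / diff.size)

    return _node(out_data, (pred,), backward)


def bce_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Binary cross-entropy on probabilities (post-sigmoid), clipped for
    numerical stability."""
    t = np.asarray(target, dtype=_DTYPE)
    p = np.clip(pred.data, eps, 1.0 - eps)
    out_data = np.array(-(t * np.log(p) + (1 - t) * np.log(1 - p)).mean(), dtype=_DTYPE)

    def backward(g):
        _accum(pred, g * (p - t) / (p * (1 - p)) / p.size)

    return _node(out_data, (pred,), backward)
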