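"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the network needs: broadcast add/mul,
batched matmul, axis-wise "same" convolution, batch normalisation, ReLU,
softmax, pooling, concatenation, reductions, and the matrix exponential of a
skew-symmetric generator (for the orthogonal projection layer).  Gradients
accumulate into ``Tensor.grad`` after :meth:`Tensor.backward`.

The engine is deliberately small: every op defines a closure that maps the
output gradient back onto its parents.  Graph construction is skipped
entirely inside :func:`no_grad` (evaluation mode), so inference allocates no
tape.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.linalg import expm, expm_frechet

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[], None] | None = None

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray, own: bool = False) -> None:
        """Add ``g`` to the gradient.  ``own=True`` asserts that ``g`` is a
        freshly allocated array no other node references, letting the first
        accumulation adopt it without a defensive copy."""
        if self.grad is None:
            if own and g.dtype == self.data.dtype:
                self.grad = g
            else:
                self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (one node per layer op)
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # break the closure↔node reference cycles and drop intermediate
        # gradients so the tape is reclaimed immediately (leaves keep theirs)
        for node in topo:
            if node._parents:
                node._backward = None
                node._parents = ()
                node.grad = None

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, Tensor(np.array(-1.0, dtype=self.data.dtype)))

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
    return out


# -- elementwise ----------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    out = _make(a.data + b.data, (a, b))
    if out.requires_grad:
        def _bw():
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(out.grad, b.shape))
        out._backward = _bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = _make(a.data * b.data, (a, b))
    if out.requires_grad:
        def _bw():
            if a.requires_grad:
                a._accumulate(_unbroadcast(out.grad * b.data, a.shape), own=True)
            if b.requires_grad:
                b._accumulate(_unbroadcast(out.grad * a.data, b.shape), own=True)
        out._backward = _bw
    return out


def relu(x: Tensor) -> Tensor:
    out = _make(np.maximum(x.data, 0), (x,))
    if out.requires_grad:
        mask = x.data > 0
        def _bw():
            x._accumulate(out.grad * mask, own=True)
        out._backward = _bw
    return out


def log(x: Tensor, clamp: float = 1e-12) -> Tensor:
    """Natural log with the argument clamped below at ``clamp``."""
    clamped = np.maximum(x.data, clamp)
    out = _make(np.log(clamped), (x,))
    if out.requires_grad:
        active = x.data >= clamp
        def _bw():
            x._accumulate(np.where(active, out.grad / clamped, 0.0))
        out._backward = _bw
    return out


# -- linear algebra --------------------------------------------------------


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = _make(np.matmul(a.data, b.data), (a, b))
    if out.requires_grad:
        def _bw():
            g = out.grad
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.shape), own=True)
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.shape), own=True)
        out._backward = _bw
    return out


def transpose_last2(x: Tensor) -> Tensor:
    out = _make(np.swapaxes(x.data, -1, -2), (x,))
    if out.requires_grad:
        def _bw():
            x._accumulate(np.swapaxes(out.grad, -1, -2))
        out._backward = _bw
    return out


def expm_skew(a: Tensor) -> Tensor:
    """P = exp(A − Aᵀ): orthogonal by construction for any square A.

    The adjoint of the Fréchet derivative of ``expm`` at S applied to G is
    the Fréchet derivative at Sᵀ applied to G; chaining through S = A − Aᵀ
    gives dA = dS − dSᵀ.
    """
    s = a.data - a.data.T
    out = _make(expm(s), (a,))
    if out.requires_grad:
        def _bw():
            ds = expm_frechet(s.T, out.grad, compute_expm=False)
            a._accumulate((ds - ds.T).astype(a.data.dtype))
        out._backward = _bw
    return out


def cast(x: Tensor, dtype) -> Tensor:
    """Dtype cast with straight-through gradient (cast back on the way up)."""
    if x.data.dtype == np.dtype(dtype):
        return x
    out = _make(x.data.astype(dtype), (x,))
    if out.requires_grad:
        def _bw():
            x._accumulate(out.grad.astype(x.data.dtype))
        out._backward = _bw
    return out


# -- shape ops -------------------------------------------------------------


def reshape(x: Tensor, shape) -> Tensor:
    out = _make(x.data.reshape(shape), (x,))
    if out.requires_grad:
        def _bw():
            x._accumulate(out.grad.reshape(x.shape))
        out._backward = _bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def _bw():
            parts = np.split(out.grad, splits, axis=axis)
            for t, g in zip(tensors, parts):
                if t.requires_grad:
                    t._accumulate(g)
        out._backward = _bw
    return out


def mean(x: Tensor, axis, keepdims: bool = False) -> Tensor:
    axes = tuple(np.atleast_1d(axis))
    out = _make(x.data.mean(axis=axes, keepdims=keepdims), (x,))
    if out.requires_grad:
        n = np.prod([x.shape[a] for a in axes])
        def _bw():
            g = out.grad
            if not keepdims:
                g = np.expand_dims(g, axes)
            x._accumulate(np.broadcast_to(g, x.shape) / n)
        out._backward = _bw
    return out


def sum_(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    axes = tuple(range(x.ndim)) if axis is None else tuple(np.atleast_1d(axis))
    out = _make(x.data.sum(axis=axes, keepdims=keepdims), (x,))
    if out.requires_grad:
        def _bw():
            g = out.grad
            if not keepdims:
                g = np.expand_dims(g, axes)
            x._accumulate(np.broadcast_to(g, x.shape).copy())
        out._backward = _bw
    return out


# -- softmax ---------------------------------------------------------------


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = _make(y, (x,))
    if out.requires_grad:
        def _bw():
            g = out.grad
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot), own=True)
        out._backward = _bw
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = _make(z - lse, (x,))
    if out.requires_grad:
        y = np.exp(out.data)
        def _bw():
            g = out.grad
            x._accumulate(g - y * g.sum(axis=axis, keepdims=True), own=True)
        out._backward = _bw
    return out


# -- convolution and pooling ----------------------------------------------


def conv1d_axis(x: Tensor, w: Tensor, b: Tensor | None, axis: int,
                stride: int = 1) -> Tensor:
    """Convolve a [N, C, H, W] map along one axis with "same" zero padding.

    ``w`` is [O, C, k] with k odd; ``axis`` is 2 (spatial, across electrodes)
    or 3 (temporal, across samples).  Output length is ceil(L / stride).
    """
    n_out, n_in, k = w.shape
    if k % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {k}")
    if k == 1:
        return _conv1x1(x, w, b, axis, stride)
    pad = k // 2
    xm = np.moveaxis(x.data, axis, -1)            # [N, C, A, L]
    n, c, a, length = xm.shape
    if c != n_in:
        raise ValueError(f"input has {c} channels, kernel expects {n_in}")
    xp = np.pad(xm, [(0, 0)] * 3 + [(pad, pad)])
    win = sliding_window_view(xp, k, axis=-1)[..., ::stride, :]
    l_out = win.shape[-2]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4))  # [N,A,Lo,C,k]
    cols2 = cols.reshape(n * a * l_out, c * k)
    w2 = w.data.reshape(n_out, c * k)
    y = cols2 @ w2.T
    if b is not None:
        y += b.data
    y = y.reshape(n, a, l_out, n_out).transpose(0, 3, 1, 2)
    out = _make(np.moveaxis(y, -1, axis) if axis != 3 else y, (x, w) if b is None else (x, w, b))
    # note: for axis==3 the layout [N,O,A,Lo] is already [N,O,H,W']

    if out.requires_grad:
        def _bw():
            g = out.grad
            gm = np.moveaxis(g, axis, -1) if axis != 3 else g   # [N,O,A,Lo]
            g2 = np.ascontiguousarray(gm.transpose(0, 2, 3, 1)).reshape(-1, n_out)
            if b is not None and b.requires_grad:
                b._accumulate(g2.sum(axis=0))
            if w.requires_grad:
                gw = g2.T @ cols2
                w._accumulate(gw.reshape(n_out, c, k))
            if x.requires_grad:
                gc = (g2 @ w2).reshape(n, a, l_out, c, k).transpose(0, 3, 1, 2, 4)
                gxp = np.zeros_like(xp)
                for j in range(k):
                    gxp[..., j:j + stride * l_out:stride] += gc[..., j]
                gx = gxp[..., pad:pad + length]
                x._accumulate(np.moveaxis(gx, -1, axis), own=True)
        out._backward = _bw
    return out


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None, axis: int,
             stride: int) -> Tensor:
    """k=1 convolution: pure channel mixing (with optional subsampling).

    Avoids the im2col copies of the general path; roughly half the
    network's convolution branches are 1×1.
    """
    xd = x.data
    if stride != 1:
        sl = [slice(None)] * 4
        sl[axis] = slice(0, None, stride)
        xd = np.ascontiguousarray(xd[tuple(sl)])
    n, c, hh, ww = xd.shape
    w2 = w.data[:, :, 0]                           # [O, C]
    xf = xd.reshape(n, c, hh * ww)
    y = np.matmul(w2, xf).reshape(n, -1, hh, ww)   # batched channel mixing
    if b is not None:
        y += b.data[None, :, None, None]
    out = _make(y, (x, w) if b is None else (x, w, b))
    if out.requires_grad:
        def _bw():
            g = out.grad
            gf = np.ascontiguousarray(g).reshape(n, -1, hh * ww)
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.matmul(gf, xf.swapaxes(1, 2)).sum(axis=0)
                w._accumulate(gw[:, :, None])
            if x.requires_grad:
                gx_s = np.matmul(w2.T, gf).reshape(xd.shape)
                if stride == 1:
                    x._accumulate(gx_s, own=True)
                else:
                    gx = np.zeros_like(x.data)
                    sl = [slice(None)] * 4
                    sl[axis] = slice(0, None, stride)
                    gx[tuple(sl)] = gx_s
                    x._accumulate(gx, own=True)
        out._backward = _bw
    return out


def channel_project(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1×1 convolution across feature channels with a single output channel.

    x: [N, C, H, W], w: [C], b: scalar → [N, 1, H, W].
    """
    y = np.einsum("nchw,c->nhw", x.data, w.data) + b.data
    out = _make(y[:, None], (x, w, b))
    if out.requires_grad:
        def _bw():
            g = out.grad[:, 0]
            if b.requires_grad:
                b._accumulate(np.asarray(g.sum()).reshape(b.shape))
            if w.requires_grad:
                w._accumulate(np.einsum("nchw,nhw->c", x.data, g))
            if x.requires_grad:
                x._accumulate(w.data[None, :, None, None] * g[:, None])
        out._backward = _bw
    return out


def maxpool_spatial(x: Tensor, size: int = 2, stride: int = 2) -> Tensor:
    """Non-overlapping max pooling along axis 2 (requires size == stride)."""
    if size != stride:
        raise ValueError("only non-overlapping pooling is supported")
    n, c, h, w = x.shape
    ho = h // size
    xv = x.data[:, :, :ho * size].reshape(n, c, ho, size, w)
    idx = xv.argmax(axis=3)
    out = _make(np.take_along_axis(xv, idx[:, :, :, None], axis=3)[:, :, :, 0], (x,))
    if out.requires_grad:
        def _bw():
            gx = np.zeros_like(x.data)
            gv = gx[:, :, :ho * size].reshape(n, c, ho, size, w)
            np.put_along_axis(gv, idx[:, :, :, None], out.grad[:, :, :, None], axis=3)
            gx[:, :, :ho * size] = gv.reshape(n, c, ho * size, w)
            x._accumulate(gx)
        out._backward = _bw
    return out


def avgpool_temporal(x: Tensor, stride: int) -> Tensor:
    """Non-overlapping average pooling along axis 3 (window = stride)."""
    if stride == 1:
        return x
    n, c, h, w = x.shape
    wo = w // stride
    out = _make(x.data[..., :wo * stride].reshape(n, c, h, wo, stride).mean(-1), (x,))
    if out.requires_grad:
        def _bw():
            gx = np.zeros_like(x.data)
            gx[..., :wo * stride] = np.repeat(out.grad, stride, axis=-1) / stride
            x._accumulate(gx)
        out._backward = _bw
    return out


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
              running_var: np.ndarray, training: bool, momentum: float = 0.1,
              eps: float = 1e-5) -> Tensor:
    """Batch normalisation per feature channel (axis 1) of a [N,C,H,W] map.

    Running statistics are updated in place during training and used verbatim
    in evaluation mode, so inference is deterministic.
    """
    from ._kernels import _bn_apply, _bn_backward_train, _bn_stats

    shape = (1, -1, 1, 1)
    dtype = x.data.dtype
    if training:
        mu, var = _bn_stats(x.data)
        mu = mu.astype(dtype)
        var = var.astype(dtype)
        running_mean += momentum * (mu - running_mean)
        running_var += momentum * (var - running_var)
    else:
        mu, var = running_mean, running_var
    inv = (1.0 / np.sqrt(var + eps)).astype(dtype)
    xhat = np.empty_like(x.data)
    y = np.empty_like(x.data)
    _bn_apply(x.data, mu.astype(dtype), inv, gamma.data.astype(dtype),
              beta.data.astype(dtype), xhat, y)
    out = _make(y, (x, gamma, beta))
    if out.requires_grad:
        def _bw():
            g = out.grad
            if training and x.requires_grad:
                gx = np.empty_like(g)
                dgamma = np.empty(g.shape[1], dtype=np.float64)
                dbeta = np.empty(g.shape[1], dtype=np.float64)
                _bn_backward_train(g, xhat, gamma.data.astype(g.dtype), inv,
                                   gx, dgamma, dbeta)
                beta._accumulate(dbeta.astype(g.dtype))
                gamma._accumulate(dgamma.astype(g.dtype))
                x._accumulate(gx, own=True)
            else:
                if beta.requires_grad:
                    beta._accumulate(g.sum(axis=(0, 2, 3)))
                if gamma.requires_grad:
                    gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
                if x.requires_grad:
                    x._accumulate(inv.reshape(shape) * g
                                  * gamma.data.reshape(shape))
        out._backward = _bw
    return out
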