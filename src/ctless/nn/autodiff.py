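"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the segmentation network needs: 3-D
convolution and transposed convolution (kernel 3, padding 1, stride 1 or 2),
pointwise (1x1x1) convolution, leaky ReLU, sigmoid, elementwise product,
channel concatenation, dropout, channel softmax, and a fused weighted
binary-cross-entropy loss.  Tensors are (channels, depth, height, width)
float32 arrays without a batch axis; minibatch gradients are formed by
accumulation over samples.  All gradients are verified against finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Tensor:
    """Node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=F32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(F32, copy=False)
        else:
            self.grad = self.grad + g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.requires_grad and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None


def _param_backward(out, pairs):
    """Build a backward closure from (tensor, grad_fn) pairs."""

    def bw(g):
        for t, fn in pairs:
            if t.requires_grad:
                t._accum(fn(g))

    return bw


# ---------------------------------------------------------------------------
# convolution primitives (kernel 3, pad 1)
# ---------------------------------------------------------------------------

def _out_spatial(in_spatial, stride: int):
    return tuple((s + 2 - 3) // stride + 1 for s in in_spatial)


def _conv_fwd(x: np.ndarray, w: np.ndarray, stride: int) -> np.ndarray:
    """Direct convolution as 27 channel-mixing GEMMs over shifted slices."""
    ci = x.shape[0]
    do, ho, wo = _out_spatial(x.shape[1:], stride)
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    out = np.zeros((w.shape[0], do * ho * wo), dtype=F32)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                sl = np.ascontiguousarray(
                    xp[:, i:i + stride * do:stride,
                       j:j + stride * ho:stride,
                       k:k + stride * wo:stride]).reshape(ci, -1)
                out += w[:, :, i, j, k] @ sl
    return out.reshape((w.shape[0], do, ho, wo))


def _conv_igrad(gy: np.ndarray, w: np.ndarray, stride: int, in_spatial) -> np.ndarray:
    """Gradient of _conv_fwd w.r.t. its input (exact adjoint)."""
    co, ci = w.shape[:2]
    d, h, wd = in_spatial
    do, ho, wo = gy.shape[1:]
    gyf = gy.reshape(co, -1)
    gxp = np.zeros((ci, d + 2, h + 2, wd + 2), dtype=F32)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                contrib = (w[:, :, i, j, k].T @ gyf).reshape(ci, do, ho, wo)
                gxp[:, i:i + stride * do:stride,
                    j:j + stride * ho:stride,
                    k:k + stride * wo:stride] += contrib
    return gxp[:, 1:-1, 1:-1, 1:-1]


def _conv_wgrad(x: np.ndarray, gy: np.ndarray, stride: int) -> np.ndarray:
    ci = x.shape[0]
    co = gy.shape[0]
    do, ho, wo = gy.shape[1:]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    gyf = gy.reshape(co, -1)
    gw = np.empty((co, ci, 3, 3, 3), dtype=F32)
    for i in range(3):
        for j in range(3):
            for k in range(3):
                sl = np.ascontiguousarray(
                    xp[:, i:i + stride * do:stride,
                       j:j + stride * ho:stride,
                       k:k + stride * wo:stride]).reshape(ci, -1)
                gw[:, :, i, j, k] = gyf @ sl.T
    return gw


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """3-D convolution, kernel 3, zero padding 1."""
    out = _conv_fwd(x.data, w.data, stride) + b.data[:, None, None, None]
    in_spatial = x.data.shape[1:]
    pairs = [
        (x, lambda g: _conv_igrad(g, w.data, stride, in_spatial)),
        (w, lambda g: _conv_wgrad(x.data, g, stride)),
        (b, lambda g: g.sum(axis=(1, 2, 3))),
    ]
    return Tensor(out, parents=(x, w, b), backward=_param_backward(None, pairs))


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 2,
                     out_spatial=None) -> Tensor:
    """Transposed 3-D convolution: the exact adjoint of :func:`conv3d`.

    ``w`` has shape (C_out, C_in, 3, 3, 3) where C_in is the channel count of
    ``x``; with stride 2 the spatial size doubles (``out_spatial`` overrides).
    """
    if out_spatial is None:
        out_spatial = tuple(s * stride for s in x.data.shape[1:])
    # forward of convT == input-gradient of a conv with weights (Ci_x, Co, k..)
    wc = w.data.transpose(1, 0, 2, 3, 4)  # conv weights: maps out->x
    out = _conv_igrad(x.data, wc, stride, out_spatial) + b.data[:, None, None, None]

    def gx(g):
        return _conv_fwd(g, wc, stride)

    def gw(g):
        return _conv_wgrad(g, x.data, stride).transpose(1, 0, 2, 3, 4)

    pairs = [(x, gx), (w, gw), (b, lambda g: g.sum(axis=(1, 2, 3)))]
    return Tensor(out, parents=(x, w, b), backward=_param_backward(None, pairs))


def pointwise_conv(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1x1x1 convolution: channel mixing, w of shape (C_out, C_in)."""
    ci = x.data.shape[0]
    xf = x.data.reshape(ci, -1)
    out = (w.data @ xf + b.data[:, None]).reshape((w.data.shape[0],) + x.data.shape[1:])
    pairs = [
        (x, lambda g: (w.data.T @ g.reshape(w.data.shape[0], -1)).reshape(x.data.shape)),
        (w, lambda g: g.reshape(w.data.shape[0], -1) @ xf.T),
        (b, lambda g: g.sum(axis=(1, 2, 3))),
    ]
    return Tensor(out, parents=(x, w, b), backward=_param_backward(None, pairs))


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, slope * x.data)
    return Tensor(out, parents=(x,),
                  backward=_param_backward(None, [(x, lambda g: np.where(mask, g, slope * g))]))


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable in both tails
    pos = x.data >= 0
    e = np.exp(np.where(pos, -x.data, x.data))
    s = np.where(pos, 1.0 / (1.0 + e), e / (1.0 + e)).astype(F32)
    return Tensor(s, parents=(x,),
                  backward=_param_backward(None, [(x, lambda g: g * s * (1.0 - s))]))


def multiply(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise product with channel broadcasting (for attention gating)."""
    out = a.data * b.data

    def ga(g):
        r = g * b.data
        return r if r.shape == a.data.shape else _unbroadcast(r, a.data.shape)

    def gb(g):
        r = g * a.data
        return r if r.shape == b.data.shape else _unbroadcast(r, b.data.shape)

    return Tensor(out, parents=(a, b), backward=_param_backward(None, [(a, ga), (b, gb)]))


def _unbroadcast(g, shape):
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    return g.sum(axis=axes, keepdims=True)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def make(t):
        def fn(g):
            return g if g.shape == t.data.shape else _unbroadcast(g, t.data.shape)
        return fn

    return Tensor(out, parents=(a, b),
                  backward=_param_backward(None, [(a, make(a)), (b, make(b))]))


def concat(tensors, axis: int = 0) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    bounds = np.cumsum([0] + sizes)

    def make(i, t):
        def fn(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(bounds[i], bounds[i + 1])
            return g[tuple(sl)]
        return fn

    pairs = [(t, make(i, t)) for i, t in enumerate(tensors)]
    return Tensor(out, parents=tuple(tensors), backward=_param_backward(None, pairs))


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(F32) / F32(1.0 - p)
    out = x.data * mask
    return Tensor(out, parents=(x,),
                  backward=_param_backward(None, [(x, lambda g: g * mask)]))


def channel_softmax(x: Tensor) -> Tensor:
    """Softmax over axis 0 (the K region channels)."""
    z = x.data - x.data.max(axis=0, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=0, keepdims=True)

    def gx(g):
        dot = (g * s).sum(axis=0, keepdims=True)
        return s * (g - dot)

    return Tensor(s, parents=(x,), backward=_param_backward(None, [(x, gx)]))


def weighted_bce(probs: Tensor, truth: np.ndarray, weights: np.ndarray,
                 eps: float = 1e-7) -> Tensor:
    """Per-voxel, per-region weighted binary cross-entropy (summed).

    ``truth`` is the (K, ...) one-hot ground truth, ``weights`` the K region
    weights.  Probabilities are clipped to [eps, 1-eps] before the logs; the
    gradient is zero where the clip is active.
    """
    p = np.clip(probs.data.astype(np.float64), eps, 1.0 - eps)
    t = np.asarray(truth, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64).reshape((-1,) + (1,) * (p.ndim - 1))
    loss = np.sum(w * (-t * np.log(p) - (1.0 - t) * np.log(1.0 - p)))
    inside = (probs.data > eps) & (probs.data < 1.0 - eps)

    def gx(g):
        grad = w * (-t / p + (1.0 - t) / (1.0 - p)) * inside
        return (g * grad).astype(F32)

    return Tensor(np.float64(loss).astype(F32),
                  parents=(probs,), backward=_param_backward(None, [(probs, gx)]))
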