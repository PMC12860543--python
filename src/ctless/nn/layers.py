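"""Parameterized layers built on the autodiff core.

Kernel weights use Glorot normal initialization; biases start at the constant
0.03.  Every layer exposes ``parameters()`` for the optimizer.
"""

from __future__ import annotations

import numpy as np

from .autodiff import (
    F32,
    Tensor,
    add,
    conv3d,
    conv_transpose3d,
    leaky_relu,
    multiply,
    pointwise_conv,
    sigmoid,
)

BIAS_INIT = 0.03


def _glorot_normal(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=shape).astype(F32)


class Conv3d:
    """3x3x3 convolution (pad 1) followed by leaky ReLU."""

    def __init__(self, c_in: int, c_out: int, stride: int = 1, *,
                 rng: np.random.Generator, leaky_slope: float = 0.1,
                 activation: bool = True):
        self.stride = stride
        self.leaky_slope = leaky_slope
        self.activation = activation
        w = _glorot_normal(rng, (c_out, c_in, 3, 3, 3), c_in * 27, c_out * 27)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.full(c_out, BIAS_INIT, dtype=F32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        y = conv3d(x, self.w, self.b, stride=self.stride)
        return leaky_relu(y, self.leaky_slope) if self.activation else y

    def parameters(self):
        return [self.w, self.b]


class ConvTranspose3d:
    """3x3x3 transposed convolution followed by leaky ReLU.

    With stride 2 the spatial size doubles; with stride 1 it is preserved.
    """

    def __init__(self, c_in: int, c_out: int, stride: int = 2, *,
                 rng: np.random.Generator, leaky_slope: float = 0.1):
        self.stride = stride
        self.leaky_slope = leaky_slope
        w = _glorot_normal(rng, (c_out, c_in, 3, 3, 3), c_in * 27, c_out * 27)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.full(c_out, BIAS_INIT, dtype=F32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        y = conv_transpose3d(x, self.w, self.b, stride=self.stride)
        return leaky_relu(y, self.leaky_slope)

    def parameters(self):
        return [self.w, self.b]


class AttentionGate:
    """Additive attention gate on a skip connection.

    The gating signal ``g`` (decoder features) and the skip features ``x``
    are projected to an intermediate channel count by pointwise convolutions,
    summed, passed through a leaky ReLU, and reduced to a single-channel
    sigmoid attention coefficient that multiplies the skip features.
    """

    def __init__(self, c_x: int, c_g: int, c_int: int, *,
                 rng: np.random.Generator, leaky_slope: float = 0.1):
        self.leaky_slope = leaky_slope
        self.wx = Tensor(_glorot_normal(rng, (c_int, c_x), c_x, c_int), requires_grad=True)
        self.bx = Tensor(np.full(c_int, BIAS_INIT, dtype=F32), requires_grad=True)
        self.wg = Tensor(_glorot_normal(rng, (c_int, c_g), c_g, c_int), requires_grad=True)
        self.bg = Tensor(np.full(c_int, BIAS_INIT, dtype=F32), requires_grad=True)
        self.wpsi = Tensor(_glorot_normal(rng, (1, c_int), c_int, 1), requires_grad=True)
        self.bpsi = Tensor(np.full(1, BIAS_INIT, dtype=F32), requires_grad=True)

    def __call__(self, x: Tensor, g: Tensor) -> Tensor:
        q = add(pointwise_conv(x, self.wx, self.bx), pointwise_conv(g, self.wg, self.bg))
        q = leaky_relu(q, self.leaky_slope)
        alpha = sigmoid(pointwise_conv(q, self.wpsi, self.bpsi))
        return multiply(x, alpha)

    def parameters(self):
        return [self.wx, self.bx, self.wg, self.bg, self.wpsi, self.bpsi]


class Adam:
    """Adam optimizer over a list of Tensors."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= (lr_t * m / (np.sqrt(v) + self.eps)).astype(F32)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
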