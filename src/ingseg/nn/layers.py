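"""Conv / batch-norm / gated-activation layers on NCHW float32 arrays.

Everything is plain numpy with hand-written backward passes; shapes are
small enough (<= 224 x 224, kernels <= 3) that per-kernel-offset tensordot
loops beat an im2col materialization on both memory and speed.
"""

from __future__ import annotations

import math

import numpy as np


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # piecewise form avoids overflow in exp for large |x|
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out.astype(x.dtype)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    z: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of softmax(z) against integer labels y.

    Returns (loss, dloss/dz); z is (N, C), y is (N,).
    """
    n, c = z.shape
    if y.min() < 0 or y.max() >= c:
        raise ValueError(f"label out of range [0, {c})")
    zs = z - z.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(zs).sum(axis=1))
    loss = float(np.mean(logsumexp - zs[np.arange(n), y]))
    p = softmax(z, axis=1)
    p[np.arange(n), y] -= 1.0
    return loss, (p / n).astype(z.dtype)


def same_padding(n: int, k: int, s: int) -> tuple[int, int, int]:
    """(pad_before, pad_after, out_size) giving out = ceil(n / s)."""
    out = math.ceil(n / s)
    total = max((out - 1) * s + k - n, 0)
    return total // 2, total - total // 2, out


class Conv2d:
    """2-D convolution with 'same' padding (output = ceil(in / stride))."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int,
        rng: np.random.Generator,
        name: str = "conv",
    ):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        std = math.sqrt(2.0 / (in_channels * kernel * kernel))
        self.weight = Parameter(
            f"{name}.weight",
            rng.normal(0.0, std, size=(out_channels, in_channels, kernel, kernel)),
        )
        self.bias = Parameter(f"{name}.bias", np.zeros(out_channels))
        self._cache: tuple | None = None

    @property
    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N, {self.in_channels}, H, W) input, got {x.shape}"
            )
        n, _, h, w = x.shape
        k, s = self.kernel, self.stride
        pt, pb, ho = same_padding(h, k, s)
        pl, pr, wo = same_padding(w, k, s)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        out = np.zeros((n, self.out_channels, ho, wo), dtype=np.float32)
        wv = self.weight.value
        for a in range(k):
            for b in range(k):
                patch = xp[:, :, a : a + s * ho : s, b : b + s * wo : s]
                # (N,Ci,Ho,Wo) x (Co,Ci) -> (N,Ho,Wo,Co)
                out += np.tensordot(patch, wv[:, :, a, b], axes=([1], [1])).transpose(
                    0, 3, 1, 2
                )
        out += self.bias.value[None, :, None, None]
        self._cache = (xp, x.shape, (pt, pl), (ho, wo))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp, x_shape, (pt, pl), (ho, wo) = self._cache
        k, s = self.kernel, self.stride
        dxp = np.zeros_like(xp)
        wv = self.weight.value
        for a in range(k):
            for b in range(k):
                patch = xp[:, :, a : a + s * ho : s, b : b + s * wo : s]
                # dW: (N,Co,Ho,Wo) x (N,Ci,Ho,Wo) summed over N,Ho,Wo
                self.weight.grad[:, :, a, b] += np.tensordot(
                    dout, patch, axes=([0, 2, 3], [0, 2, 3])
                )
                # dx: (N,Co,Ho,Wo) x (Co,Ci) -> (N,Ho,Wo,Ci)
                dxp[:, :, a : a + s * ho : s, b : b + s * wo : s] += np.tensordot(
                    dout, wv[:, :, a, b], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        self.bias.grad += dout.sum(axis=(0, 2, 3))
        _, _, h, w = x_shape
        return dxp[:, :, pt : pt + h, pl : pl + w]


class BatchNorm2d:
    """Per-channel batch normalization with running inference statistics."""

    def __init__(self, channels: int, name: str = "bn", momentum: float = 0.1,
                 eps: float = 1e-5):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(f"{name}.gamma", np.ones(channels))
        self.beta = Parameter(f"{name}.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache: tuple | None = None

    @property
    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                np.float32
            )
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                np.float32
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat
        out += self.beta.value[None, :, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, train, x_shape = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return (dout * g * inv_std[None, :, None, None]).astype(np.float32)
        n, _, h, w = x_shape
        m = n * h * w
        dxhat = dout * g
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        return (term * inv_std[None, :, None, None]).astype(np.float32)


class _SigmoidGate:
    """y = u * sigmoid(u): the sigmoid activation score multiplied back in."""

    def __init__(self):
        self._cache: tuple | None = None

    def forward(self, u: np.ndarray) -> np.ndarray:
        s = sigmoid(u)
        self._cache = (u, s)
        return (u * s).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        u, s = self._cache
        return (dout * (s + u * s * (1.0 - s))).astype(np.float32)


class GatedBlock:
    """conv -> batch-norm -> sigmoid score -> element-wise multiplication."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int,
        rng: np.random.Generator,
        name: str = "block",
    ):
        self.conv = Conv2d(in_channels, out_channels, kernel, stride, rng,
                           name=f"{name}.conv")
        self.bn = BatchNorm2d(out_channels, name=f"{name}.bn")
        self.gate = _SigmoidGate()
        self.name = name

    @property
    def in_channels(self) -> int:
        return self.conv.in_channels

    @property
    def out_channels(self) -> int:
        return self.conv.out_channels

    @property
    def kernel(self) -> int:
        return self.conv.kernel

    @property
    def stride(self) -> int:
        return self.conv.stride

    @property
    def params(self) -> list[Parameter]:
        return self.conv.params + self.bn.params

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.gate.forward(self.bn.forward(self.conv.forward(x), train))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.gate.backward(dout)))


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C) spatial mean."""
    return x.mean(axis=(2, 3))


def global_avg_pool_backward(dpooled: np.ndarray, spatial: tuple[int, int]) -> np.ndarray:
    h, w = spatial
    return np.broadcast_to(
        dpooled[:, :, None, None] / (h * w), dpooled.shape + (h, w)
    ).astype(np.float32)
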