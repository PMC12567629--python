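"""Minimal NumPy neural-network engine with manual backpropagation.

Provides exactly the pieces the WideResNet family needs: 1-D and 2-D
convolutions (im2col + GEMM), batch normalization, ReLU, global average
pooling, a linear classifier and SGD with momentum.  Everything runs in
single precision.

Internally all feature maps are channels-last ([B, L, C] / [B, H, W, C]),
which keeps the im2col gather and the GEMM output contiguous and avoids
transposed copies on the CPU; the network front-end converts from the
public channels-first convention once per forward pass.

Each layer caches what its backward pass needs during
``forward(train=True)``; calling ``backward`` immediately after a training
forward propagates gradients and accumulates them into ``Parameter.grad``.

Determinism: all weight initialization draws come from a caller-supplied
``numpy.random.Generator`` in construction order, and the forward/backward
math is plain BLAS, so fixed seeds give bit-identical runs on a fixed
BLAS build.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Conv1d",
    "Conv2d",
    "BatchNorm",
    "ReLU",
    "GlobalAvgPool",
    "Linear",
    "SGD",
]


class Parameter:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class keeping named parameters, buffers and children in
    registration order (the order defines the flattened weight vector)."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}

    # -- registration -----------------------------------------------------
    def add_module(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    # -- traversal --------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for cname, child in self._children.items():
            yield from child.named_buffers(prefix + cname + ".")

    def modules(self):
        yield self
        for child in self._children.values():
            yield from child.modules()

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv1d(Module):
    """Bias-free 1-D convolution on [B, L, C] maps, 'same' padding.

    Weight layout is (c_out, kernel * c_in), matching the (k, C) order of
    the flattened im2col patch.
    """

    def __init__(self, c_in, c_out, kernel, stride=1, *, rng):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2
        self._params["weight"] = Parameter(
            _he_normal(rng, (c_out, kernel * c_in), kernel * c_in)
        )
        self._cache = None

    @property
    def weight(self):
        return self._params["weight"]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (0, 0))) if p else np.ascontiguousarray(x)
        Lout = (L + 2 * p - k) // s + 1
        # k slice-assignments beat one generic strided gather on the CPU
        cols4 = np.empty((B, Lout, k, C), dtype=np.float32)
        for i in range(k):
            cols4[:, :, i, :] = xp[:, i : i + s * Lout : s, :]
        cols = cols4.reshape(B * Lout, k * C)
        out = cols @ self.weight.data.T
        if train:
            self._cache = (cols, (B, L, C), Lout)
        return out.reshape(B, Lout, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (B, L, C), Lout = self._cache
        self._cache = None
        k, s, p = self.kernel, self.stride, self.pad
        d2 = np.ascontiguousarray(dout).reshape(B * Lout, self.c_out)
        self.weight.grad += d2.T @ cols
        dcols = (d2 @ self.weight.data).reshape(B, Lout, k, C)
        dxp = np.zeros((B, L + 2 * p, C), dtype=np.float32)
        for i in range(k):
            dxp[:, i : i + s * Lout : s, :] += dcols[:, :, i, :]
        return dxp[:, p : p + L, :] if p else dxp


class Conv2d(Module):
    """Bias-free 2-D convolution on [B, H, W, C] maps, square kernels,
    'same' padding.  Weight layout is (c_out, kernel * kernel * c_in)."""

    def __init__(self, c_in, c_out, kernel, stride=1, *, rng):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2
        fan_in = c_in * kernel * kernel
        self._params["weight"] = Parameter(_he_normal(rng, (c_out, fan_in), fan_in))
        self._cache = None

    @property
    def weight(self):
        return self._params["weight"]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, H, W, C = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        xp = (
            np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
            if p
            else np.ascontiguousarray(x)
        )
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        cols6 = np.empty((B, Ho, Wo, k, k, C), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                cols6[:, :, :, i, j, :] = xp[
                    :, i : i + s * Ho : s, j : j + s * Wo : s, :
                ]
        cols = cols6.reshape(B * Ho * Wo, k * k * C)
        out = cols @ self.weight.data.T
        if train:
            self._cache = (cols, (B, H, W, C), (Ho, Wo))
        return out.reshape(B, Ho, Wo, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (B, H, W, C), (Ho, Wo) = self._cache
        self._cache = None
        k, s, p = self.kernel, self.stride, self.pad
        d2 = np.ascontiguousarray(dout).reshape(B * Ho * Wo, self.c_out)
        self.weight.grad += d2.T @ cols
        dcols = (d2 @ self.weight.data).reshape(B, Ho, Wo, k, k, C)
        dxp = np.zeros((B, H + 2 * p, W + 2 * p, C), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + s * Ho : s, j : j + s * Wo : s, :] += dcols[
                    :, :, :, i, j, :
                ]
        return dxp[:, p : p + H, p : p + W, :] if p else dxp


class BatchNorm(Module):
    """Batch normalization per channel (last axis), affine.

    Modes: training (batch statistics, EMA update of running stats),
    evaluation (running stats), and an accumulation mode used to
    re-estimate running statistics for interpolated weight vectors —
    one pass over data in accumulation mode replaces the EMA with the
    plain average of per-batch statistics.
    """

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self._params["gamma"] = Parameter(np.ones(channels))
        self._params["beta"] = Parameter(np.zeros(channels))
        self._buffers["running_mean"] = np.zeros(channels, dtype=np.float32)
        self._buffers["running_var"] = np.ones(channels, dtype=np.float32)
        self.accumulating = False
        self._acc_mean = None
        self._acc_var = None
        self._acc_n = 0
        self._cache = None

    def start_accumulate(self):
        self.accumulating = True
        self._acc_mean = np.zeros(self.channels, dtype=np.float64)
        self._acc_var = np.zeros(self.channels, dtype=np.float64)
        self._acc_n = 0

    def finish_accumulate(self):
        if self._acc_n > 0:
            self._buffers["running_mean"][...] = (self._acc_mean / self._acc_n).astype(
                np.float32
            )
            self._buffers["running_var"][...] = (self._acc_var / self._acc_n).astype(
                np.float32
            )
        self.accumulating = False
        self._acc_mean = self._acc_var = None
        self._acc_n = 0

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        C = self.channels
        g = self._params["gamma"].data
        b = self._params["beta"].data
        if train or self.accumulating:
            x2 = x.reshape(-1, C)
            n = x2.shape[0]
            s = np.einsum("nc->c", x2)
            ss = np.einsum("nc,nc->c", x2, x2)
            mu = s / n
            var = np.maximum(ss / n - mu * mu, 0.0)
            if self.accumulating:
                self._acc_mean += mu
                self._acc_var += var * (n / max(n - 1, 1))
                self._acc_n += 1
            elif train:
                m = self.momentum
                unbiased = var * (n / max(n - 1, 1))
                self._buffers["running_mean"] *= 1 - m
                self._buffers["running_mean"] += m * mu
                self._buffers["running_var"] *= 1 - m
                self._buffers["running_var"] += m * unbiased
            istd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
            # out = x * (g istd) + (b - mu g istd), two in-place passes
            scale = g * istd
            out = x * scale
            out += b - mu * scale
            if train:
                self._cache = (x, mu, istd, n)
            return out
        mu = self._buffers["running_mean"]
        istd = 1.0 / np.sqrt(self._buffers["running_var"] + self.eps)
        scale = (g * istd).astype(np.float32)
        out = x * scale
        out += b - mu * scale
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, mu, istd, n = self._cache
        self._cache = None
        C = self.channels
        g = self._params["gamma"].data
        d2 = dout.reshape(-1, C)
        x2 = x.reshape(-1, C)
        sd = d2.sum(axis=0)
        sdx = np.einsum("nc,nc->c", d2, x2)
        # dgamma = sum(dout * xhat) with xhat recomputed from x
        dgamma = (sdx - mu * sd) * istd
        self._params["gamma"].grad += dgamma
        self._params["beta"].grad += sd
        # dx = A*dout + D*x + E with per-channel coefficients
        gi = g * istd
        A = gi
        D = -(gi * istd / n) * dgamma
        E = -(gi / n) * sd - D * mu
        dx = dout * A
        dx += x * D
        dx += E
        return dx


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return dout * mask


class GlobalAvgPool(Module):
    """Mean over all spatial axes of a channels-last map -> [B, C]."""

    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=tuple(range(1, x.ndim - 1)))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        shape, self._shape = self._shape, None
        n_spatial = int(np.prod(shape[1:-1]))
        expanded = dout[:, None] if len(shape) == 3 else dout[:, None, None]
        return np.broadcast_to(expanded / n_spatial, shape).astype(np.float32).copy()


class Linear(Module):
    """Affine map with bias."""

    def __init__(self, n_in, n_out, *, rng):
        super().__init__()
        self._params["weight"] = Parameter(_he_normal(rng, (n_out, n_in), n_in))
        self._params["bias"] = Parameter(np.zeros(n_out))
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self._params["weight"].data.T + self._params["bias"].data

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, self._cache = self._cache, None
        self._params["weight"].grad += dout.T @ x
        self._params["bias"].grad += dout.sum(axis=0)
        return dout @ self._params["weight"].data


class SGD:
    """SGD with momentum and (coupled) weight decay, per the classic
    ``v <- mu v + g + wd w;  w <- w - lr v`` update."""

    def __init__(self, params, momentum=0.9, weight_decay=1e-4):
        self.params = list(params)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float):
        mu, wd = self.momentum, self.weight_decay
        for p, v in zip(self.params, self.velocity):
            g = p.grad + wd * p.data
            v *= mu
            v += g
            p.data -= np.float32(lr) * v

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
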