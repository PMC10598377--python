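"""Minimal neural-network layers with explicit backpropagation.

Every layer caches what its backward pass needs during ``forward`` and
releases it on ``backward``; a model is therefore used strictly in
forward-then-backward order within one optimisation step.  All arrays are
``float32``; all randomness comes from a caller-supplied
:class:`numpy.random.Generator`, which makes whole training runs bitwise
reproducible on one machine.

Conventions
-----------
* Volumetric activations are ``(N, C, D, H, W)`` (batch, channels, depth,
  height, width).
* Convolutions are bias-free (a batch-norm always follows them).
* ``train=True`` selects batch statistics in batch-norm; ``train=False``
  uses running statistics and is fully deterministic.
"""

from __future__ import annotations

import itertools
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: working dtype of all parameters and activations.  float32 is the
#: default; tests may set float64 for high-precision gradient checks
#: (set before constructing a model).
DTYPE = np.float32

__all__ = [
    "Param",
    "Module",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool3d",
    "AdaptiveAvgPool3d",
    "Linear",
    "Sequential",
    "Adam",
    "batchnorm_layers",
    "collect_batchnorm_stats",
    "load_batchnorm_stats",
]


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class: parameter enumeration plus forward/backward contract."""

    def params(self) -> list[Param]:
        out: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def state(self) -> list[np.ndarray]:
        """Snapshot of all parameter values (deep copies, stable order)."""
        return [p.value.copy() for p in self.params()]

    def load_state(self, values: Iterable[np.ndarray]) -> None:
        for p, v in zip(self.params(), values, strict=True):
            if p.value.shape != v.shape:
                raise ValueError(
                    f"state shape mismatch: {p.value.shape} vs {v.shape}"
                )
            p.value[...] = v


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected scalar or length-3, got {v!r}")
    return t


class Conv3d(Module):
    """3-D cross-correlation, stride/padding per axis, no bias.

    Uses an im2col/GEMM formulation: sliding windows are materialised once
    per forward pass into a contiguous column matrix that both the forward
    product and the two backward products reuse.  He-normal initialisation
    (fan-in), matching the ReLU nonlinearity used throughout the encoder.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size=3,
        stride=1,
        padding=1,
        *,
        rng: np.random.Generator,
    ):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = _triple(kernel_size)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        fan_in = in_channels * int(np.prod(self.kernel))
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Param(
            rng.normal(0.0, std, (out_channels, in_channels) + self.kernel)
        )
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.ndim != 5 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (N,{self.in_channels},D,H,W), got {x.shape}"
            )
        pd, ph, pw = self.padding
        sd, sh, sw = self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
        win = sliding_window_view(xp, self.kernel, axis=(2, 3, 4))
        win = win[:, :, ::sd, ::sh, ::sw]  # (B, C, Do, Ho, Wo, kd, kh, kw)
        b, c, do, ho, wo = win.shape[:5]
        k3 = int(np.prod(self.kernel))
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
            b * do * ho * wo, c * k3
        )
        wmat = self.weight.value.reshape(self.out_channels, c * k3)
        out = (cols @ wmat.T).reshape(b, do, ho, wo, self.out_channels)
        self._cache = (cols, xp.shape, (b, do, ho, wo))
        return np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._cache is not None, "backward before forward"
        cols, xp_shape, (b, do, ho, wo) = self._cache
        self._cache = None
        c, k3 = self.in_channels, int(np.prod(self.kernel))
        wmat = self.weight.value.reshape(self.out_channels, c * k3)
        doutmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 4, 1)).reshape(
            -1, self.out_channels
        )
        self.weight.grad += (doutmat.T @ cols).reshape(self.weight.value.shape)
        dcols = (doutmat @ wmat).reshape(
            b, do, ho, wo, c, *self.kernel
        )
        sd, sh, sw = self.stride
        kd, kh, kw = self.kernel
        dxp = np.zeros(xp_shape, dtype=DTYPE)
        for i, j, k in itertools.product(range(kd), range(kh), range(kw)):
            # scatter the contribution of kernel tap (i,j,k) back onto x
            dxp[
                :,
                :,
                i : i + sd * do : sd,
                j : j + sh * ho : sh,
                k : k + sw * wo : sw,
            ] += dcols[..., i, j, k].transpose(0, 4, 1, 2, 3)
        pd, ph, pw = self.padding
        d, h, w_ = dxp.shape[2:]
        return dxp[:, :, pd : d - pd or None, ph : h - ph or None, pw : w_ - pw or None]


class BatchNorm3d(Module):
    """Per-channel batch normalisation over (N, D, H, W) with affine terms."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        shape = (1, -1, 1, 1, 1)
        xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
        if train:
            self._cache = (xhat, invstd)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._cache is not None, "backward before training-mode forward"
        xhat, invstd = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        n = dout.size // dout.shape[1]
        g = self.gamma.value.reshape(shape)
        dxhat = dout * g
        # standard batch-norm backward (batch statistics)
        dx = (
            invstd.reshape(shape)
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=axes).reshape(shape)
                - xhat * (dxhat * xhat).sum(axis=axes).reshape(shape)
            )
        )
        return dx.astype(DTYPE)


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return np.where(mask, dout, 0.0).astype(DTYPE)


class MaxPool3d(Module):
    """2x2x2 max pooling with stride 2; odd extents are padded with -inf."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, d, h, w = x.shape
        pd, ph, pw = d % 2, h % 2, w % 2
        if pd or ph or pw:
            x = np.pad(
                x,
                ((0, 0), (0, 0), (0, pd), (0, ph), (0, pw)),
                constant_values=-np.inf,
            )
        n, c, d, h, w = x.shape
        xr = (
            x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 6, 3, 5, 7)
            .reshape(n, c, d // 2, h // 2, w // 2, 8)
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (n, c, d, h, w), (pd, ph, pw))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, padded_shape, (pd, ph, pw) = self._cache
        self._cache = None
        n, c, d, h, w = padded_shape
        dxr = np.zeros(dout.shape + (8,), dtype=DTYPE)
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        dx = (
            dxr.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 2, 5, 3, 6, 4, 7)
            .reshape(n, c, d, h, w)
        )
        return dx[:, :, : d - pd, : h - ph, : w - pw]


class AdaptiveAvgPool3d(Module):
    """Global average pooling to a single spatial cell; output (N, C)."""

    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._shape
        self._shape = None
        scale = 1.0 / (d * h * w)
        return np.broadcast_to(
            (dout * scale)[:, :, None, None, None], (n, c, d, h, w)
        ).astype(DTYPE)


class Linear(Module):
    """Affine layer ``y = x W^T + b`` with He-normal weights."""

    def __init__(self, in_features: int, out_features: int, *, rng: np.random.Generator):
        self.in_features = in_features
        self.out_features = out_features
        std = float(np.sqrt(2.0 / in_features))
        self.weight = Param(rng.normal(0.0, std, (out_features, in_features)))
        self.bias = Param(np.zeros(out_features))
        self._x = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.in_features:
            raise ValueError(f"expected (N,{self.in_features}), got {x.shape}")
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, self._x = self._x, None
        self.weight.grad += dout.T @ x
        self.bias.grad += dout.sum(axis=0)
        return (dout @ self.weight.value).astype(DTYPE)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def batchnorm_layers(module: Module) -> list["BatchNorm3d"]:
    """All BatchNorm3d layers reachable from ``module``, in traversal order."""
    found: list[BatchNorm3d] = []
    for v in module.__dict__.values():
        if isinstance(v, BatchNorm3d):
            found.append(v)
        elif isinstance(v, Module):
            found.extend(batchnorm_layers(v))
        elif isinstance(v, (list, tuple)):
            for item in v:
                if isinstance(item, Module):
                    found.extend(batchnorm_layers(item))
    return found


def collect_batchnorm_stats(module: Module) -> list[np.ndarray]:
    """Running mean/var of every batch-norm layer (copies, stable order)."""
    out: list[np.ndarray] = []
    for bn in batchnorm_layers(module):
        out.append(bn.running_mean.copy())
        out.append(bn.running_var.copy())
    return out


def load_batchnorm_stats(module: Module, stats: list[np.ndarray]) -> None:
    layers = batchnorm_layers(module)
    if len(stats) != 2 * len(layers):
        raise ValueError(f"expected {2 * len(layers)} stat arrays, got {len(stats)}")
    for i, bn in enumerate(layers):
        bn.running_mean[...] = stats[2 * i]
        bn.running_var[...] = stats[2 * i + 1]


class Adam:
    """Adam with (coupled) L2 weight decay added to the gradient."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
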