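"""Minimal neural-network layer built on :mod:`phasegan.autodiff`.

Contains exactly the building blocks the imputation networks use: linear and
3x3-convolutional layers (im2col), instance / layer / batch normalization,
conditional instance normalization (CIN) driven by a latent vector, and an
Adam optimizer.  Normalizations are written as compositions of differentiable
primitives, so they remain valid under the double backward used by the
gradient penalty.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, grad, unfold

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Conv2d",
    "InstanceNorm2d",
    "ConditionalInstanceNorm2d",
    "LayerNorm2d",
    "BatchNorm2d",
    "Adam",
    "set_default_dtype",
    "get_default_dtype",
]

_EPS = 1e-5

# float32 keeps training fast on a single CPU; switch to float64 for
# high-precision gradient checks.
_DEFAULT_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    """Set the dtype used for newly created parameters (float32/float64)."""
    global _DEFAULT_DTYPE
    dtype = np.dtype(dtype).type
    if dtype not in (np.float32, np.float64):
        raise ValueError("default dtype must be float32 or float64")
    _DEFAULT_DTYPE = dtype


def get_default_dtype():
    return _DEFAULT_DTYPE


class Parameter(Tensor):
    """A trainable tensor (stored at the layer default dtype)."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=_DEFAULT_DTYPE), requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
        return params

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in vars(self).items():
            _, val = v
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for p, arr in zip(params, state):
            if p.data.shape != arr.shape:
                raise ValueError("parameter shape mismatch in state dict")
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    @property
    def dtype(self):
        return self.parameters()[0].data.dtype

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = math.sqrt(2.0 / n_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """k x k convolution via im2col; ``stride`` > 1 downsamples."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        ksize: int = 3,
        stride: int = 1,
        padding: int | None = None,
    ):
        super().__init__()
        self.ksize = ksize
        self.stride = stride
        self.padding = (ksize - 1) // 2 if padding is None else padding
        fan_in = c_in * ksize * ksize
        scale = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(c_out, fan_in)))
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        b, _, h, w = x.shape
        ho = (h + 2 * self.padding - self.ksize) // self.stride + 1
        wo = (w + 2 * self.padding - self.ksize) // self.stride + 1
        cols = unfold(x, self.ksize, self.stride, self.padding)
        out = self.weight @ cols  # [B, c_out, ho*wo] by broadcasting
        out = out + self.bias.reshape((1, -1, 1))
        return out.reshape((b, self.weight.shape[0], ho, wo))


def _normalize(x: Tensor, axes: tuple[int, ...]) -> Tensor:
    mu = x.mean(axis=axes, keepdims=True)
    xc = x - mu
    var = (xc**2.0).mean(axis=axes, keepdims=True)
    return xc * (var + _EPS) ** -0.5


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over spatial dimensions."""

    def forward(self, x: Tensor) -> Tensor:
        return _normalize(x, (2, 3))


class ConditionalInstanceNorm2d(Module):
    """Instance normalization with latent-dependent scale and shift.

    gamma(z) and beta(z) are affine maps of the latent vector; gamma is
    initialized around 1 so the layer starts close to plain instance norm.
    This is how stochasticity enters the generator at every scale.
    """

    def __init__(self, n_channels: int, latent_dim: int, rng: np.random.Generator):
        super().__init__()
        self.gamma = Linear(latent_dim, n_channels, rng)
        self.beta = Linear(latent_dim, n_channels, rng)

    def forward(self, x: Tensor, z: Tensor) -> Tensor:
        xn = _normalize(x, (2, 3))
        b, c = x.shape[0], x.shape[1]
        gamma = (1.0 + self.gamma(z)).reshape((b, c, 1, 1))
        beta = self.beta(z).reshape((b, c, 1, 1))
        return xn * gamma + beta


class LayerNorm2d(Module):
    """Normalization over (C, H, W) per sample, with per-channel affine."""

    def __init__(self, n_channels: int):
        super().__init__()
        self.scale = Parameter(np.ones((1, n_channels, 1, 1)))
        self.shift = Parameter(np.zeros((1, n_channels, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        return _normalize(x, (1, 2, 3)) * self.scale + self.shift


class BatchNorm2d(Module):
    """Batch normalization with running statistics for evaluation mode."""

    def __init__(self, n_channels: int, momentum: float = 0.1):
        super().__init__()
        self.scale = Parameter(np.ones((1, n_channels, 1, 1)))
        self.shift = Parameter(np.zeros((1, n_channels, 1, 1)))
        self.momentum = momentum
        self.running_mean = np.zeros((1, n_channels, 1, 1), dtype=_DEFAULT_DTYPE)
        self.running_var = np.ones((1, n_channels, 1, 1), dtype=_DEFAULT_DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc**2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
            xn = xc * (var + _EPS) ** -0.5
        else:
            xn = (x - Tensor(self.running_mean)) * Tensor(
                (self.running_var + _EPS) ** -0.5
            )
        return xn * self.scale + self.shift


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.5, 0.9),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads: list[Tensor]) -> None:
        if len(grads) != len(self.params):
            raise ValueError("gradient list does not match parameter list")
        self.t += 1
        b1, b2 = self.b1, self.b2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for i, (p, g) in enumerate(zip(self.params, grads)):
            gd = g.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * gd
            self.v[i] = b2 * self.v[i] + (1 - b2) * gd * gd
            p.data = p.data - self.lr * (self.m[i] / bias1) / (
                np.sqrt(self.v[i] / bias2) + self.eps
            )

    def state(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state(self, state: dict) -> None:
        self.t = state["t"]
        self.m = [m.copy() for m in state["m"]]
        self.v = [v.copy() for v in state["v"]]


def parameter_grads(loss: Tensor, params: list[Parameter]) -> list[Tensor]:
    """Convenience wrapper: gradients of a scalar loss w.r.t. parameters."""
    return grad(loss, params)
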