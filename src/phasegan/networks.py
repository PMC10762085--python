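"""Generator and critic architectures.

The generator is a U-Net over the 4-phase sequence, built from dense blocks
DB(k, n): n sub-blocks of (normalization -> activation -> 3x3 convolution)
with concatenative connectivity, where each sub-block but the last emits k
growth features.  Down blocks coarsen the spatial resolution by a factor p
(strided convolution) while multiplying channels by q; Up blocks refine by p
(nearest-neighbour upsample + convolution) while dividing channels by q, and
concatenate the skip features from the matching scale.  The latent vector z
enters at every scale of both branches through conditional instance
normalization (CIN), and an outer skip connection adds the U-Net output to
the input sequence, so the network predicts a residual perturbation:
x^G = y + Delta(y, z).

The critic shares the dense-block downsampling trunk (with layer
normalization instead of CIN, since it takes no latent input), followed by a
fully connected head emitting one scalar per (x, y) pair.

Both specs are scale-parameterized so a tiny CPU instance (32x32, two
scales) and a full 128x128 instance share one code path; ``n_scales=0``
degenerates to a single-scale network, which is what the 1x1 "image"
sanity problems use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, leaky_relu, relu, upsample_nearest
from .nn import (
    BatchNorm2d,
    ConditionalInstanceNorm2d,
    Conv2d,
    InstanceNorm2d,
    LayerNorm2d,
    Linear,
    Module,
)

__all__ = [
    "GeneratorSpec",
    "CriticSpec",
    "Generator",
    "Critic",
    "sample_latent",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Scale parameters of the dense-block U-Net generator."""

    image_size: int = 32
    n_phases: int = 4
    latent_dim: int = 8  # 50 at full 128x128 scale
    n_scales: int = 2
    base_channels: int = 8
    growth_k: int = 4
    block_n: int = 2
    down_p: int = 2
    chan_q: int = 2
    outer_skip: bool = True
    norm: str = "cin"  # "cin" (stochastic) or "batch" (pix2pix variant)
    # Scale of the final 3x3 convolution's weight init.  Small but non-zero:
    # the untrained generator starts near the identity on y while still
    # passing gradient to the latent pathway.
    final_init_scale: float = 0.01

    def validate(self) -> None:
        if self.latent_dim < 1 and self.norm == "cin":
            raise ValueError("latent_dim must be >= 1 for a CIN generator")
        if self.image_size % (self.down_p**self.n_scales) != 0:
            raise ValueError(
                "image_size must be divisible by down_p ** n_scales"
            )
        if self.norm not in ("cin", "batch"):
            raise ValueError("generator norm must be 'cin' or 'batch'")


@dataclass(frozen=True)
class CriticSpec:
    """Scale parameters of the dense-block critic."""

    image_size: int = 32
    in_channels: int = 8  # x and y concatenated, 4 phases each
    n_scales: int = 2
    base_channels: int = 8
    growth_k: int = 4
    block_n: int = 2
    down_p: int = 2
    chan_q: int = 2
    fc_widths: tuple[int, ...] = (64,)

    def validate(self) -> None:
        if self.image_size % (self.down_p**self.n_scales) != 0:
            raise ValueError(
                "image_size must be divisible by down_p ** n_scales"
            )


def sample_latent(
    rng: np.random.Generator, batch: int, latent_dim: int
) -> np.ndarray:
    """Draw z ~ N(0, I) of shape [batch, latent_dim]."""
    return rng.normal(0.0, 1.0, size=(batch, latent_dim))


class _Norm(Module):
    """Dispatches to CIN / batch / layer norm with a uniform call signature."""

    def __init__(self, kind: str, channels: int, latent_dim: int, rng):
        super().__init__()
        self.kind = kind
        if kind == "cin":
            self.norm = ConditionalInstanceNorm2d(channels, latent_dim, rng)
        elif kind == "batch":
            self.norm = BatchNorm2d(channels)
        elif kind == "layer":
            self.norm = LayerNorm2d(channels)
        elif kind == "instance":
            self.norm = InstanceNorm2d()
        else:
            raise ValueError(f"unknown norm kind {kind!r}")

    def forward(self, x: Tensor, z: Tensor | None) -> Tensor:
        if self.kind == "cin":
            if z is None:
                raise ValueError("CIN requires a latent vector")
            return self.norm(x, z)
        return self.norm(x)


class DenseBlock(Module):
    """DB(k, n): concatenative sub-blocks of norm -> activation -> conv.

    Sub-blocks 1..n-1 emit ``k`` growth features each, which are concatenated
    onto the running feature stack; the last sub-block maps the stack to
    ``c_out`` and its output is the block output.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        n: int,
        norm: str,
        latent_dim: int,
        rng,
        activation=relu,
    ):
        super().__init__()
        self.activation = activation
        self.norms: list[_Norm] = []
        self.convs: list[Conv2d] = []
        c = c_in
        for i in range(n):
            last = i == n - 1
            self.norms.append(_Norm(norm, c, latent_dim, rng))
            self.convs.append(Conv2d(c, c_out if last else k, rng))
            c += k
        self.c_out = c_out

    def forward(self, x: Tensor, z: Tensor | None = None) -> Tensor:
        stack = x
        out = x
        for i, (norm, conv) in enumerate(zip(self.norms, self.convs)):
            h = conv(self.activation(norm(stack, z)))
            if i < len(self.convs) - 1:
                stack = concat([stack, h], axis=1)
            out = h
        return out


class DownBlock(Module):
    """Dense block followed by a strided convolution (x p coarser, x q channels)."""

    def __init__(self, c_in, k, n, p, q, norm, latent_dim, rng, activation=relu):
        super().__init__()
        self.block = DenseBlock(c_in, c_in, k, n, norm, latent_dim, rng, activation)
        self.down = Conv2d(c_in, c_in * q, rng, ksize=p, stride=p, padding=0)

    def forward(self, x, z=None):
        skip = self.block(x, z)
        return self.down(skip), skip


class UpBlock(Module):
    """Nearest upsample + conv (x p finer, / q channels), skip concat, dense block."""

    def __init__(self, c_in, skip_c, k, n, p, q, norm, latent_dim, rng, activation=relu):
        super().__init__()
        self.p = p
        self.up = Conv2d(c_in, c_in // q, rng)
        self.block = DenseBlock(
            c_in // q + skip_c, skip_c, k, n, norm, latent_dim, rng, activation
        )

    def forward(self, x, skip, z=None):
        h = self.up(upsample_nearest(x, self.p))
        return self.block(concat([h, skip], axis=1), z)


class Generator(Module):
    """Dense-block U-Net with latent injection and outer skip: x^G = y + Delta."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__()
        spec.validate()
        self.spec = spec
        s = spec
        self.head = Conv2d(s.n_phases, s.base_channels, rng)
        self.downs: list[DownBlock] = []
        c = s.base_channels
        for _ in range(s.n_scales):
            self.downs.append(
                DownBlock(c, s.growth_k, s.block_n, s.down_p, s.chan_q,
                          s.norm, s.latent_dim, rng)
            )
            c *= s.chan_q
        self.bottleneck = DenseBlock(
            c, c, s.growth_k, s.block_n, s.norm, s.latent_dim, rng
        )
        self.ups: list[UpBlock] = []
        for _ in range(s.n_scales):
            skip_c = c // s.chan_q
            self.ups.append(
                UpBlock(c, skip_c, s.growth_k, s.block_n, s.down_p, s.chan_q,
                        s.norm, s.latent_dim, rng)
            )
            c = skip_c
        # Near-identity start: tiny final-layer weights keep x^G ~ y early on.
        self.final = Conv2d(c, s.n_phases, rng)
        self.final.weight.data[:] = (
            s.final_init_scale
            * rng.standard_normal(self.final.weight.shape)
        ).astype(self.final.weight.data.dtype)
        self.final.bias.data[:] = 0.0

    def forward(self, y: Tensor | np.ndarray, z: Tensor | np.ndarray | None = None) -> Tensor:
        if not isinstance(y, Tensor):
            y = Tensor(np.asarray(y, dtype=self.dtype))
        if z is not None and not isinstance(z, Tensor):
            z = Tensor(np.asarray(z, dtype=self.dtype))
        h = self.head(y)
        skips = []
        for down in self.downs:
            h, skip = down(h, z)
            skips.append(skip)
        h = self.bottleneck(h, z)
        for up, skip in zip(self.ups, reversed(skips)):
            h = up(h, skip, z)
        delta = self.final(h)
        return y + delta if self.spec.outer_skip else delta


class Critic(Module):
    """Dense-block downsampler + fully connected head -> one scalar per pair."""

    def __init__(self, spec: CriticSpec, rng: np.random.Generator):
        super().__init__()
        spec.validate()
        self.spec = spec
        s = spec
        self.head = Conv2d(s.in_channels, s.base_channels, rng)
        self.downs: list[DownBlock] = []
        c = s.base_channels
        for _ in range(s.n_scales):
            self.downs.append(
                DownBlock(c, s.growth_k, s.block_n, s.down_p, s.chan_q,
                          "layer", 0, rng, activation=leaky_relu)
            )
            c *= s.chan_q
        self.trunk_tail = DenseBlock(
            c, c, s.growth_k, s.block_n, "layer", 0, rng, activation=leaky_relu
        )
        spatial = s.image_size // (s.down_p**s.n_scales)
        width = c * spatial * spatial
        self.fcs: list[Linear] = []
        for w in s.fc_widths:
            self.fcs.append(Linear(width, w, rng))
            width = w
        self.out = Linear(width, 1, rng)

    def forward(
        self, x: Tensor | np.ndarray, y: Tensor | np.ndarray
    ) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.dtype))
        if not isinstance(y, Tensor):
            y = Tensor(np.asarray(y, dtype=self.dtype))
        if x.shape != y.shape:
            raise ValueError("x and y must share shape [B, 4, H, W]")
        h = self.head(concat([x, y], axis=1))
        for down in self.downs:
            h, _ = down(h)
        h = self.trunk_tail(h)
        b = h.shape[0]
        h = h.reshape((b, -1))
        for fc in self.fcs:
            h = leaky_relu(fc(h))
        return self.out(h).reshape((b,))
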