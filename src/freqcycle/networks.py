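"""3D VNet generator and 3D PatchGAN discriminator.

The generator is an encoder-decoder with an input block (kernel-5 conv,
instance norm, PReLU), four down-sampling blocks with (1, 2, 3, 2)
convolutional blocks, four up-sampling blocks with (2, 2, 1, 1), UNet-style
skip connections and an output block whose last convolution is followed by
tanh, so outputs live in (-1, 1).  Each down stage ends in a stride-2
convolution; striding along z is disabled in the last two stages so a
16-slice patch (z halving at most twice) remains admissible while in-plane
dimensions halve at all four stages.

The discriminator is the canonical PatchGAN lifted to 3D: a few strided
convolutions ending in a 1-channel score grid whose every element judges a
local patch (raw scores, suitable for the least-squares adversarial loss).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, concat

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "build_generator",
    "build_discriminator",
    "VNet3D",
    "PatchGAN3D",
]


@dataclass(frozen=True)
class GeneratorSpec:
    in_channels: int = 1
    base_filters: int = 16
    down_block_convs: tuple = (1, 2, 3, 2)
    up_block_convs: tuple = (2, 2, 1, 1)
    norm: str = "instance"
    activation: str = "prelu"
    final_activation: str = "tanh"
    # z-striding only in the first `z_stride_stages` down stages
    z_stride_stages: int = 2

    def __post_init__(self):
        if self.norm != "instance":
            raise ValueError("only instance normalization is supported")
        if self.activation != "prelu":
            raise ValueError("only PReLU activation is supported")
        if self.final_activation != "tanh":
            raise ValueError("the generator must end in tanh")
        if len(self.down_block_convs) != len(self.up_block_convs):
            raise ValueError("down and up stage counts must match")

    @property
    def n_stages(self) -> int:
        return len(self.down_block_convs)

    def stage_strides(self) -> list[tuple]:
        return [
            (2, 2, 2) if i < self.z_stride_stages else (1, 2, 2)
            for i in range(self.n_stages)
        ]

    def divisibility(self) -> tuple:
        """Required input-shape divisors (z, y, x)."""
        dz = 2 ** min(self.z_stride_stages, self.n_stages)
        dxy = 2 ** self.n_stages
        return (dz, dxy, dxy)


@dataclass(frozen=True)
class DiscriminatorSpec:
    in_channels: int = 1
    n_layers: int = 3
    base_filters: int = 64


def _conv_block(cin, cout, rng, kernel=3, stride=1):
    pad = tuple(k // 2 for k in ((kernel,) * 3 if isinstance(kernel, int) else kernel))
    return nn.Sequential(
        nn.Conv3d(cin, cout, kernel, stride=stride, padding=pad, rng=rng),
        nn.InstanceNorm3d(cout),
        nn.PReLU(cout),
    )


class VNet3D(nn.Module):
    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        f = spec.base_filters
        strides = spec.stage_strides()

        self.input_block = _conv_block(spec.in_channels, f, rng, kernel=5)

        self.down_blocks = []
        self.down_strided = []
        ch = f
        self.skip_channels = []
        for i, n_convs in enumerate(spec.down_block_convs):
            blocks = [_conv_block(ch, ch, rng) for _ in range(n_convs)]
            self.down_blocks.append(nn.Sequential(*blocks))
            self.skip_channels.append(ch)
            self.down_strided.append(_conv_block(ch, ch * 2, rng, stride=strides[i]))
            ch *= 2

        self.up_trans = []
        self.up_blocks = []
        for i, n_convs in enumerate(spec.up_block_convs):
            stride = strides[spec.n_stages - 1 - i]
            self.up_trans.append(nn.ConvTranspose3d(ch, ch // 2, stride=stride, rng=rng))
            skip = self.skip_channels[spec.n_stages - 1 - i]
            merged = ch // 2 + skip
            blocks = [_conv_block(merged if j == 0 else ch // 2, ch // 2, rng)
                      for j in range(max(1, n_convs))]
            self.up_blocks.append(nn.Sequential(*blocks))
            ch //= 2

        self.out_conv1 = _conv_block(ch, ch, rng)
        self.out_conv2 = nn.Conv3d(ch, spec.in_channels, 3, padding=1, rng=rng)
        self.out_act = nn.Tanh()

    def _check_shape(self, shape) -> None:
        div = self.spec.divisibility()
        spatial = shape[2:]
        for n, d, name in zip(spatial, div, "zyx"):
            if n % d != 0 or n < d:
                raise ValueError(
                    f"generator input {name}-dimension {n} must be a positive multiple of {d} "
                    f"(input shape {tuple(spatial)}, required divisors {div})"
                )

    def forward(self, x: Tensor) -> Tensor:
        self._check_shape(x.shape)
        h = self.input_block(x)
        skips = []
        for block, strided in zip(self.down_blocks, self.down_strided):
            h = block(h)
            skips.append(h)
            h = strided(h)
        for trans, block, skip in zip(self.up_trans, self.up_blocks, reversed(skips)):
            h = trans(h)
            h = concat([h, skip], axis=1)
            h = block(h)
        h = self.out_conv1(h)
        h = self.out_conv2(h)
        return self.out_act(h)


class PatchGAN3D(nn.Module):
    """3D PatchGAN: the output is a grid of raw patch scores, not a single
    image-level decision, and the receptive field is far smaller than a
    nominal training patch."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        self.spec = spec
        f = spec.base_filters
        layers = [
            nn.Conv3d(spec.in_channels, f, (3, 4, 4), stride=(2, 2, 2), padding=1, rng=rng),
            nn.LeakyReLU(0.2),
        ]
        ch = f
        for i in range(1, spec.n_layers):
            nxt = min(ch * 2, f * 8)
            layers += [
                nn.Conv3d(ch, nxt, (3, 4, 4), stride=(1, 2, 2), padding=1, rng=rng),
                nn.InstanceNorm3d(nxt),
                nn.LeakyReLU(0.2),
            ]
            ch = nxt
        layers += [nn.Conv3d(ch, 1, (3, 4, 4), stride=1, padding=1, rng=rng)]
        self.net = nn.Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


def build_generator(spec: GeneratorSpec | None = None, seed: int = 0) -> VNet3D:
    """Build a VNet generator with normal(0, 0.02) weight init under ``seed``."""
    return VNet3D(spec or GeneratorSpec(), np.random.default_rng(seed))


def build_discriminator(spec: DiscriminatorSpec | None = None, seed: int = 0) -> PatchGAN3D:
    return PatchGAN3D(spec or DiscriminatorSpec(), np.random.default_rng(seed))
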