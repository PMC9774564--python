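"""The three trainable components of the framework.

* Generator — an image-transformation network (downsampling convolutions,
  five residual blocks, upsampling convolutions) mapping luminance in
  [-1, 1] to two chroma channels in [-1, 1] via a tanh head. Batch norm +
  ReLU follow every convolution except the output layer.
* Segmenter — a plain U-Net with skip connections, mapping a 3-channel
  color image to a per-pixel foreground probability (sigmoid head).
* Discriminator — a residual-block classifier in the ResNet-style, ending
  in global average pooling and a single sigmoid probability. Two
  independent instances serve as the full-image and masked-image critics:
  same topology, separate weights.

Channel widths and image size are configurable so a desk-scale model
(64x64, narrow channels) trains on one CPU; the named profiles expose the
desk configuration and the full-scale 256x256 configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, concat

__all__ = [
    "NetworkConfig",
    "PROFILES",
    "Generator",
    "Segmenter",
    "Discriminator",
    "make_generator",
    "make_segmenter",
    "make_discriminator",
]

_DOWNSAMPLE_FACTOR = 8  # discriminator halves the grid three times


@dataclass(frozen=True)
class NetworkConfig:
    image_size: int = 256
    base_channels: int = 32
    n_residual_blocks: int = 5
    n_downsample: int = 2  # stride-2 stages in the generator encoder
    norm: str = "batch"
    discriminator_depth: str = "resnet18-like"

    def validate(self) -> None:
        factor = max(_DOWNSAMPLE_FACTOR, 2**self.n_downsample)
        if self.image_size % factor != 0:
            raise ValueError(
                f"image_size must be divisible by {factor}, got {self.image_size}"
            )
        if self.base_channels < 1 or self.n_residual_blocks < 1:
            raise ValueError("base_channels and n_residual_blocks must be >= 1")
        if self.n_downsample < 1:
            raise ValueError("n_downsample must be >= 1")
        if self.norm != "batch":
            raise ValueError(f"unsupported norm {self.norm!r}")


# The desk profile scales the full 256-pixel architecture down
# proportionally: at 64 px one stride-2 stage gives the residual blocks the
# same relative receptive field that two stages give at 256 px, and narrow
# channels keep a CPU-only training run tractable.
PROFILES: dict[str, NetworkConfig] = {
    "desk": NetworkConfig(image_size=64, base_channels=6, n_downsample=1),
    "full": NetworkConfig(image_size=256, base_channels=32, n_downsample=2),
}


def _conv_bn_relu(cin, cout, k, rng, stride=1):
    return nn.Sequential(
        nn.Conv2d(cin, cout, k, rng, stride=stride),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
    )


class Generator(nn.Module):
    """Luminance (N, 1, H, W) in [-1, 1] -> chroma (N, 2, H, W) in [-1, 1]."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        f = cfg.base_channels
        enc = [_conv_bn_relu(1, f, 7, rng)]
        ch = f
        for _ in range(cfg.n_downsample):
            enc.append(_conv_bn_relu(ch, 2 * ch, 3, rng, stride=2))
            ch *= 2
        self.encoder = nn.Sequential(*enc)
        self.blocks = nn.Sequential(
            *[nn.ResidualBlock(ch, rng) for _ in range(cfg.n_residual_blocks)]
        )
        dec = []
        for _ in range(cfg.n_downsample):
            dec.extend([nn.Upsample(2), _conv_bn_relu(ch, ch // 2, 3, rng)])
            ch //= 2
        self.decoder = nn.Sequential(*dec)
        self.head = nn.Conv2d(f, 2, 7, rng)  # no norm/activation before tanh

    def forward(self, x: Tensor) -> Tensor:
        h = self.decoder(self.blocks(self.encoder(x)))
        return self.head(h).tanh()


class Segmenter(nn.Module):
    """Color image (N, 3, H, W) -> foreground probability (N, 1, H, W)."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        f = cfg.base_channels
        self.enc0 = _conv_bn_relu(3, f, 3, rng)
        self.down0 = _conv_bn_relu(f, 2 * f, 3, rng, stride=2)
        self.enc1 = _conv_bn_relu(2 * f, 2 * f, 3, rng)
        self.down1 = _conv_bn_relu(2 * f, 4 * f, 3, rng, stride=2)
        self.bottleneck = _conv_bn_relu(4 * f, 4 * f, 3, rng)
        self.up1 = nn.Sequential(nn.Upsample(2), _conv_bn_relu(4 * f, 2 * f, 3, rng))
        self.dec1 = _conv_bn_relu(4 * f, 2 * f, 3, rng)  # input: up1 + skip(enc1)
        self.up0 = nn.Sequential(nn.Upsample(2), _conv_bn_relu(2 * f, f, 3, rng))
        self.dec0 = _conv_bn_relu(2 * f, f, 3, rng)  # input: up0 + skip(enc0)
        self.head = nn.Conv2d(f, 1, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        s0 = self.enc0(x)
        s1 = self.enc1(self.down0(s0))
        h = self.bottleneck(self.down1(s1))
        h = self.dec1(concat([self.up1(h), s1], axis=1))
        h = self.dec0(concat([self.up0(h), s0], axis=1))
        return self.head(h).sigmoid()


class Discriminator(nn.Module):
    """Color image (N, 3, H, W) -> probability of being real, in (0, 1)."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        f = cfg.base_channels
        self.features = nn.Sequential(
            _conv_bn_relu(3, f, 3, rng, stride=2),
            nn.ResidualBlock(f, rng),
            _conv_bn_relu(f, 2 * f, 3, rng, stride=2),
            nn.ResidualBlock(2 * f, rng),
            _conv_bn_relu(2 * f, 4 * f, 3, rng, stride=2),
            nn.ResidualBlock(4 * f, rng),
        )
        self.classifier = nn.Linear(4 * f, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.features(x).mean(axis=(2, 3))  # global average pool
        return self.classifier(h).sigmoid()


def make_generator(cfg: NetworkConfig, rng: np.random.Generator) -> Generator:
    return Generator(cfg, rng)


def make_segmenter(cfg: NetworkConfig, rng: np.random.Generator) -> Segmenter:
    return Segmenter(cfg, rng)


def make_discriminator(cfg: NetworkConfig, rng: np.random.Generator) -> Discriminator:
    return Discriminator(cfg, rng)
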