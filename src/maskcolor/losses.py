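"""Loss terms of the mask-guided colorization objective.

Generator/segmenter side minimizes

    L_total_g = L_gan1_g + L_gan2_g + lambda_col * L_col + lambda_seg * L_seg

where L_col is an L1 color loss on chroma plus its mask-weighted copy,
L_gan1/L_gan2 are standard cross-entropy adversarial losses on the full and
mask-weighted recomposed color images, and L_seg is per-pixel binary
cross-entropy of the segmenter against the ground-truth foreground map.
The discriminators minimize the negated two-term objective; the generator
uses the non-saturating -log D(fake) form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor
from .spatial_mask import SpatialMask, apply_mask

__all__ = [
    "LossWeights",
    "LossBundle",
    "color_loss",
    "gan_losses",
    "gan1_losses",
    "gan2_losses",
    "seg_loss",
    "total_losses",
]

_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    lambda_col: float = 1.0
    lambda_seg: float = 1.0
    enable_color: bool = True
    enable_gan1: bool = True
    enable_gan2: bool = True

    def validate(self) -> None:
        if self.lambda_col < 0 or self.lambda_seg < 0:
            raise ValueError("loss weights must be >= 0")
        if not (self.enable_color or self.enable_gan1 or self.enable_gan2):
            raise ValueError(
                "degenerate objective: at least one of color/gan1/gan2 must be enabled"
            )


@dataclass
class LossBundle:
    color: float = 0.0
    gan1_d: float = 0.0
    gan1_g: float = 0.0
    gan2_d: float = 0.0
    gan2_g: float = 0.0
    seg: float = 0.0
    total_g: float = 0.0
    total_d: float = 0.0


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def color_loss(pred_uv, true_uv, mask: SpatialMask) -> Tensor:
    """L1 chroma loss plus its mask-weighted copy, both averaged over
    all pixels and channels: mean|p - t| + mean|p*Ms - t*Ms|."""
    pred = _as_tensor(pred_uv)
    true = _as_tensor(true_uv)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, true {true.shape}")
    plain = (pred - true).abs().mean()
    masked = (apply_mask(pred, mask) - apply_mask(true, mask)).abs().mean()
    return plain + masked


def gan_losses(d_real, d_fake) -> tuple[Tensor, Tensor]:
    """Two-player objective from discriminator scores in (0, 1).

    Returns ``(d_term, g_term)``: the discriminator minimizes
    -[log D(real) + log(1 - D(fake))]; the generator minimizes the
    non-saturating -log D(fake).
    """
    r = _as_tensor(d_real).clip(_EPS, 1.0 - _EPS)
    f = _as_tensor(d_fake).clip(_EPS, 1.0 - _EPS)
    d_term = -(r.log() + (1.0 - f).log()).mean()
    g_term = -(f.log()).mean()
    return d_term, g_term


# the full-image and mask-weighted adversarial losses share one functional form
gan1_losses = gan_losses
gan2_losses = gan_losses


def seg_loss(prob_map, truth) -> Tensor:
    """Mean binary cross-entropy of the segmenter output against the
    ground-truth foreground map (1 = foreground, 0 = background)."""
    p = _as_tensor(prob_map)
    m = np.asarray(truth, dtype=np.float64)
    if p.shape != m.shape:
        raise ValueError(f"shape mismatch: prob {p.shape}, truth {m.shape}")
    if not np.all((m == 0.0) | (m == 1.0)):
        raise ValueError("truth map must be binary {0, 1}")
    p = p.clip(_EPS, 1.0 - _EPS)
    mt = Tensor(m)
    return -(mt * p.log() + (1.0 - mt) * (1.0 - p).log()).mean()


def total_losses(
    weights: LossWeights,
    color: Tensor | float = 0.0,
    gan1_d: Tensor | float = 0.0,
    gan1_g: Tensor | float = 0.0,
    gan2_d: Tensor | float = 0.0,
    gan2_g: Tensor | float = 0.0,
    seg: Tensor | float = 0.0,
) -> tuple[Tensor, Tensor, LossBundle]:
    """Combine the enabled terms into generator-side and discriminator-side
    totals; disabled terms contribute exactly zero.

    Returns ``(total_g, total_d, bundle)`` where the totals keep their
    autodiff graphs and the bundle holds detached float values for logging.
    """
    weights.validate()
    zero = Tensor(0.0)
    color_t = _as_tensor(color) if weights.enable_color else zero
    g1d = _as_tensor(gan1_d) if weights.enable_gan1 else zero
    g1g = _as_tensor(gan1_g) if weights.enable_gan1 else zero
    g2d = _as_tensor(gan2_d) if weights.enable_gan2 else zero
    g2g = _as_tensor(gan2_g) if weights.enable_gan2 else zero
    seg_t = _as_tensor(seg)

    total_g = g1g + g2g + weights.lambda_col * color_t + weights.lambda_seg * seg_t
    total_d = g1d + g2d
    bundle = LossBundle(
        color=color_t.item(),
        gan1_d=g1d.item(),
        gan1_g=g1g.item(),
        gan2_d=g2d.item(),
        gan2_g=g2g.item(),
        seg=seg_t.item(),
        total_g=total_g.item(),
        total_d=total_d.item(),
    )
    for name in ("color", "gan1_d", "gan1_g", "gan2_d", "gan2_g", "seg", "total_g", "total_d"):
        if not np.isfinite(getattr(bundle, name)):
            raise FloatingPointError(f"non-finite loss term: {name}")
    return total_g, total_d, bundle
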