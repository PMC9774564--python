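"""Foreground spatial masks: hard thresholding and Gumbel-softmax relaxation.

The segmentation branch emits a per-pixel foreground probability p. At
inference the mask is the hard indicator 1{p >= threshold}. During training
a hard mask would block gradients, so the binary choice per pixel is
relaxed with the Gumbel-softmax trick: with class log-probabilities
(log p, log(1-p)) perturbed by i.i.d. Gumbel(0, 1) noises (g1, g0) and
temperature tau, the relaxed mask value is

    Ms = exp((log p + g1)/tau) / [exp((log p + g1)/tau) + exp((log(1-p) + g0)/tau)]
       = sigmoid(((log p - log(1-p)) + (g1 - g0)) / tau)

which is differentiable in p and converges to a one-hot (binary) sample as
tau -> 0. The training schedule starts tau at 1.0 and decays it linearly to
a floor over the epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "MaskConfig",
    "SpatialMask",
    "hard_mask",
    "sample_gumbel",
    "relaxed_mask",
    "temperature_at",
    "apply_mask",
]

_EPS = 1e-6


@dataclass(frozen=True)
class MaskConfig:
    threshold: float = 0.5
    tau_start: float = 1.0
    tau_min: float = 0.1
    hard_at_inference: bool = True

    def validate(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if not self.tau_start >= self.tau_min > 0.0:
            raise ValueError(
                f"need tau_start >= tau_min > 0, got {self.tau_start}, {self.tau_min}"
            )


@dataclass
class SpatialMask:
    """Per-pixel foreground weights; ``values`` is a numpy array (hard mode)
    or an autodiff :class:`Tensor` (relaxed mode, gradients attached)."""

    values: np.ndarray | Tensor
    mode: str  # "hard" | "relaxed"

    def numpy(self) -> np.ndarray:
        return self.values.data if isinstance(self.values, Tensor) else self.values


def hard_mask(prob_map: np.ndarray, threshold: float = 0.5) -> SpatialMask:
    """Binary mask: 1 where ``prob >= threshold`` (boundary inclusive)."""
    prob = np.asarray(prob_map, dtype=np.float64)
    if prob.min() < 0.0 or prob.max() > 1.0:
        raise ValueError("prob_map values must lie in [0, 1]")
    return SpatialMask(values=(prob >= threshold).astype(np.float64), mode="hard")


def sample_gumbel(shape, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. Gumbel(0, 1) field: g = -log(-log(u)), u ~ Uniform(0, 1)."""
    u = rng.uniform(np.finfo(float).tiny, 1.0, size=shape)
    return -np.log(-np.log(u))


def relaxed_mask(
    prob_map: np.ndarray | Tensor,
    tau: float,
    g1: np.ndarray,
    g0: np.ndarray,
) -> SpatialMask:
    """Differentiable Gumbel-softmax relaxation of the binary mask."""
    if tau <= 0:
        raise ValueError(f"temperature must be > 0, got {tau}")
    p = prob_map if isinstance(prob_map, Tensor) else Tensor(prob_map)
    p = p.clip(_EPS, 1.0 - _EPS)
    # two-class softmax written as a sigmoid of the logit difference, which
    # is the numerically stable (max-subtracted) form
    a1 = (p.log() + Tensor(np.asarray(g1, dtype=np.float64))) * (1.0 / tau)
    a0 = ((1.0 - p).log() + Tensor(np.asarray(g0, dtype=np.float64))) * (1.0 / tau)
    return SpatialMask(values=(a1 - a0).sigmoid(), mode="relaxed")


def temperature_at(epoch: int, max_epochs: int, cfg: MaskConfig = MaskConfig()) -> float:
    """Linear decay from ``tau_start`` at epoch 0 with floor ``tau_min``."""
    cfg.validate()
    if not 0 <= epoch <= max_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {max_epochs}]")
    return max(cfg.tau_start * (1.0 - epoch / max_epochs), cfg.tau_min)


def apply_mask(image: np.ndarray | Tensor, mask: SpatialMask):
    """Element-wise product, mask broadcast across the channel axis.

    ``image`` is (C, H, W); returns the same type as the inputs (a Tensor if
    either operand carries gradients).
    """
    values = mask.values
    img_shape = image.shape if isinstance(image, Tensor) else np.shape(image)
    m_shape = values.shape if isinstance(values, Tensor) else np.shape(values)
    if img_shape[-2:] != m_shape[-2:]:
        raise ValueError(f"spatial size mismatch: image {img_shape}, mask {m_shape}")
    if isinstance(image, Tensor) or isinstance(values, Tensor):
        img_t = image if isinstance(image, Tensor) else Tensor(image)
        m_t = values if isinstance(values, Tensor) else Tensor(values)
        return img_t * m_t
    return np.asarray(image) * values
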