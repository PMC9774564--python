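"""RGB <-> YUV conversion and value-range mapping.

The colorizer regresses chrominance in the YUV color space: Y carries the
grayscale intensity, U and V the chroma. We use the full-range BT.601
definition, the conventional "YUV" of image processing. Raw U lies in
[-0.436, 0.436] and raw V in [-0.615, 0.615]; both are rescaled linearly to
[-1, 1] so a tanh output head covers the whole chroma gamut symmetrically.
Network inputs/outputs live in [-1, 1]; storage arrays live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "U_MAX",
    "V_MAX",
    "YuvImage",
    "rgb_to_yuv",
    "yuv_to_rgb",
    "to_network_range",
    "from_network_range",
]

U_MAX = 0.436
V_MAX = 0.615

# BT.601 full-range matrix (rows: Y, U, V), built exactly from the luma row
# so that U = U_MAX/(1 - Kb) * (B - Y) and V = V_MAX/(1 - Kr) * (R - Y);
# achromatic inputs then map to exactly zero chroma.
_KR, _KG, _KB = 0.299, 0.587, 0.114
_RGB_TO_YUV = np.array(
    [
        [_KR, _KG, _KB],
        [-_KR * U_MAX / (1 - _KB), -_KG * U_MAX / (1 - _KB), U_MAX],
        [V_MAX, -_KG * V_MAX / (1 - _KR), -_KB * V_MAX / (1 - _KR)],
    ]
)
_YUV_TO_RGB = np.linalg.inv(_RGB_TO_YUV)


@dataclass
class YuvImage:
    """Luminance ``y`` (H, W) in [0, 1] and normalized chroma ``uv`` (H, W, 2) in [-1, 1]."""

    y: np.ndarray
    uv: np.ndarray


def rgb_to_yuv(rgb: np.ndarray) -> YuvImage:
    """Convert an (H, W, 3) RGB array in [0, 1] to a :class:`YuvImage`."""
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB array, got shape {rgb.shape}")
    yuv = rgb @ _RGB_TO_YUV.T
    y = yuv[..., 0]
    uv = yuv[..., 1:] / np.array([U_MAX, V_MAX])
    return YuvImage(y=y, uv=uv)


def yuv_to_rgb(img: YuvImage) -> np.ndarray:
    """Invert :func:`rgb_to_yuv`; out-of-gamut results are clipped to [0, 1]."""
    y = np.asarray(img.y, dtype=np.float64)
    uv = np.asarray(img.uv, dtype=np.float64)
    if uv.shape != y.shape + (2,):
        raise ValueError(
            f"uv shape {uv.shape} inconsistent with y shape {y.shape}"
        )
    yuv = np.concatenate(
        [y[..., None], uv * np.array([U_MAX, V_MAX])], axis=-1
    )
    rgb = yuv @ _YUV_TO_RGB.T
    return np.clip(rgb, 0.0, 1.0)


def to_network_range(v: np.ndarray) -> np.ndarray:
    """Affine map [0, 1] -> [-1, 1] applied channelwise."""
    return 2.0 * np.asarray(v, dtype=np.float64) - 1.0


def from_network_range(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_network_range`."""
    return (np.asarray(v, dtype=np.float64) + 1.0) / 2.0
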