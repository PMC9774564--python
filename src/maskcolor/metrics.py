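"""Image-quality metrics (MAE, PSNR, SSIM) and per-background evaluation.

Metrics are computed on recomposed RGB images in [0, 1]; MAE can optionally
be computed on the chroma channels instead (``space="uv"``). SSIM follows
the canonical formulation: 11x11 Gaussian window with sigma 1.5,
K1 = 0.01, K2 = 0.03, dynamic range 1.0, population (not sample)
covariance, averaged over the valid interior of the SSIM map.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .colorspace import rgb_to_yuv

__all__ = ["mae", "psnr", "ssim", "evaluate", "PSNR_CAP"]

PSNR_CAP = 100.0  # sentinel for identical images (MSE = 0)

_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = 3.5  # radius int(3.5 * 1.5 + 0.5) = 5 -> 11x11 window
_SSIM_K1 = 0.01
_SSIM_K2 = 0.03


def _check_pair(a, b):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mae(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute difference over all pixels and channels."""
    a, b = _check_pair(a, b)
    return float(np.abs(a - b).mean())


def psnr(a: np.ndarray, b: np.ndarray, max_value: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; identical images return the cap."""
    a, b = _check_pair(a, b)
    mse = float(((a - b) ** 2).mean())
    if mse == 0.0:
        return PSNR_CAP
    return min(10.0 * np.log10(max_value**2 / mse), PSNR_CAP)


def _ssim_single(a: np.ndarray, b: np.ndarray, data_range: float) -> float:
    radius = int(_SSIM_TRUNCATE * _SSIM_SIGMA + 0.5)
    if min(a.shape) < 2 * radius + 1:
        raise ValueError(
            f"image smaller than the {2 * radius + 1}x{2 * radius + 1} SSIM window"
        )

    def f(x):
        return gaussian_filter(x, sigma=_SSIM_SIGMA, truncate=_SSIM_TRUNCATE)

    ux, uy = f(a), f(b)
    uxx, uyy, uxy = f(a * a), f(b * b), f(a * b)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    c1 = (_SSIM_K1 * data_range) ** 2
    c2 = (_SSIM_K2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux * ux + uy * uy + c1) * (vx + vy + c2)
    )
    interior = s[radius:-radius, radius:-radius]
    return float(interior.mean())


def ssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Mean structural similarity; color inputs are averaged per channel."""
    a, b = _check_pair(a, b)
    if a.ndim == 2:
        return _ssim_single(a, b, data_range)
    if a.ndim == 3:
        return float(
            np.mean([_ssim_single(a[..., c], b[..., c], data_range) for c in range(a.shape[-1])])
        )
    raise ValueError(f"expected 2-D or 3-D image, got ndim {a.ndim}")


def evaluate(colorizer, samples, mae_space: str = "rgb") -> pd.DataFrame:
    """Per-background-condition metrics plus an unweighted "Average" row.

    ``colorizer`` is a callable ``gray (H, W) in [0, 1] -> rgb (H, W, 3)``
    or an object exposing ``.colorize`` with that signature (extra return
    values are ignored). ``samples`` is an iterable of
    :class:`~maskcolor.phantom.PhantomSample`.
    """
    if mae_space not in ("rgb", "uv"):
        raise ValueError(f"mae_space must be 'rgb' or 'uv', got {mae_space!r}")
    fn = getattr(colorizer, "colorize", colorizer)
    by_condition: dict[str, list] = {}
    for s in samples:
        by_condition.setdefault(s.background_mode, []).append(s)

    rows = []
    for condition, group in sorted(by_condition.items()):
        if not group:
            warnings.warn(f"condition {condition!r} has no images; skipped")
            continue
        maes, psnrs, ssims = [], [], []
        for s in group:
            out = fn(s.y)
            rgb = out[0] if isinstance(out, tuple) else out
            if mae_space == "uv":
                maes.append(mae(rgb_to_yuv(rgb).uv, s.uv))
            else:
                maes.append(mae(rgb, s.rgb))
            psnrs.append(psnr(rgb, s.rgb))
            ssims.append(ssim(rgb, s.rgb))
        rows.append(
            {
                "condition": condition,
                "mae": float(np.mean(maes)),
                "psnr": float(np.mean(psnrs)),
                "ssim": float(np.mean(ssims)),
                "n_images": len(group),
            }
        )
    report = pd.DataFrame(rows)
    average = {
        "condition": "Average",
        "mae": report["mae"].mean(),
        "psnr": report["psnr"].mean(),
        "ssim": report["ssim"].mean(),
        "n_images": int(report["n_images"].sum()),
    }
    return pd.concat([report, pd.DataFrame([average])], ignore_index=True)
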