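"""Synthetic cryosection-like phantom images with exact foreground maps.

Real training data for medical-image colorization consists of color
cross-section photographs of tissue on an approximately uniform background,
with a curated binary foreground map per image. The phantoms emulate that
structure: a handful of elliptical "tissue" regions whose chroma is a
deterministic function of their luminance class, rendered on a swappable
background (black, white, or a smooth textured gray field). Because chroma
is a function of quantized luminance inside the foreground, a perfect
colorizer exists by construction, and the exact foreground map stands in
for the manually refined segmentation maps of real datasets.

All randomness is keyed by ``(spec.seed, index)``; the foreground geometry,
tissue assignment and luminance-noise streams are independent of the
background mode, so regenerating the same sample with a different
background changes nothing inside the foreground.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .colorspace import YuvImage, yuv_to_rgb

__all__ = [
    "BACKGROUND_MODES",
    "DEFAULT_PALETTE",
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "generate_dataset",
    "swap_background",
    "save_dataset",
    "load_dataset",
]

BACKGROUND_MODES = ("black", "white", "textured")

# (luminance level, (u, v) in normalized [-1, 1] chroma); loosely tissue-like
# colors (muscle, fluid, organ, fat), all in RGB gamut with noise margin.
DEFAULT_PALETTE: tuple[tuple[float, tuple[float, float]], ...] = (
    (0.35, (-0.10, 0.35)),
    (0.50, (0.20, -0.18)),
    (0.62, (-0.15, 0.22)),
    (0.78, (-0.22, 0.10)),
)

_MIN_LEVEL_GAP = 0.05
_COVERAGE_RANGE = (0.10, 0.80)
_MAX_GEOMETRY_TRIES = 200


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one phantom family."""

    height: int = 64
    width: int = 64
    n_tissues: int = 4
    tissue_palette: tuple[tuple[float, tuple[float, float]], ...] = DEFAULT_PALETTE
    n_blobs: int = 5
    background_mode: str = "black"
    noise_sd: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ValueError(f"height/width too small: {self.height}x{self.width}")
        if self.n_blobs < 1:
            raise ValueError(f"n_blobs must be >= 1, got {self.n_blobs}")
        if not 1 <= self.n_tissues <= len(self.tissue_palette):
            raise ValueError(
                f"n_tissues must be in [1, {len(self.tissue_palette)}], got {self.n_tissues}"
            )
        if self.background_mode not in BACKGROUND_MODES:
            raise ValueError(
                f"background_mode must be one of {BACKGROUND_MODES}, got {self.background_mode!r}"
            )
        if not 0.0 <= self.noise_sd <= 0.1:
            raise ValueError(f"noise_sd must be in [0, 0.1], got {self.noise_sd}")
        levels = [lev for lev, _ in self.tissue_palette[: self.n_tissues]]
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                if abs(levels[i] - levels[j]) < _MIN_LEVEL_GAP:
                    raise ValueError(
                        "tissue_palette luminance levels must differ by >= "
                        f"{_MIN_LEVEL_GAP}: levels {levels[i]} and {levels[j]} collide"
                    )
        for lev, (u, v) in self.tissue_palette[: self.n_tissues]:
            if not (0.0 <= lev <= 1.0 and -1.0 <= u <= 1.0 and -1.0 <= v <= 1.0):
                raise ValueError(
                    f"tissue_palette entry out of range: ({lev}, ({u}, {v}))"
                )


@dataclass
class PhantomSample:
    """One paired (color image, luminance, chroma, foreground map) sample."""

    rgb: np.ndarray  # (H, W, 3) in [0, 1]
    y: np.ndarray  # (H, W) in [0, 1]
    uv: np.ndarray  # (H, W, 2) in [-1, 1]
    foreground: np.ndarray  # (H, W) binary {0, 1}
    background_mode: str
    spec: PhantomSpec | None = field(default=None, repr=False)
    index: int | None = None

    @property
    def foreground_fraction(self) -> float:
        return float(self.foreground.mean())


def _blob_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Seeded blob parameters with coverage in the valid range (rejection).

    The first blob is a large "body" cross-section; the remaining blobs are
    organ-sized structures placed near the body center and painted over it
    (painter's algorithm, later blobs win). This mirrors the morphology of
    cryosection slices, where the foreground is one large connected region
    with internal tissue structure, rather than scattered small islands.
    """
    h, w = spec.height, spec.width
    size = min(h, w)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(_MAX_GEOMETRY_TRIES):
        fg = np.zeros((h, w), dtype=np.int64)
        tissue = np.full((h, w), -1, dtype=np.int64)
        body_cx = body_cy = None
        for blob in range(spec.n_blobs):
            if blob == 0:
                a = rng.uniform(0.28, 0.42) * size
                b = rng.uniform(0.28, 0.42) * size
            else:
                a = rng.uniform(0.08, 0.18) * size
                b = rng.uniform(0.08, 0.18) * size
            theta = rng.uniform(0.0, np.pi)
            ext_x = np.hypot(a * np.cos(theta), b * np.sin(theta))
            ext_y = np.hypot(a * np.sin(theta), b * np.cos(theta))
            if blob == 0:
                cx = rng.uniform(ext_x, w - 1 - ext_x)
                cy = rng.uniform(ext_y, h - 1 - ext_y)
                body_cx, body_cy = cx, cy
            else:
                cx = np.clip(
                    body_cx + rng.uniform(-0.15, 0.15) * size, ext_x, w - 1 - ext_x
                )
                cy = np.clip(
                    body_cy + rng.uniform(-0.15, 0.15) * size, ext_y, h - 1 - ext_y
                )
            k = int(rng.integers(0, spec.n_tissues))
            dx, dy = xx - cx, yy - cy
            u = dx * np.cos(theta) + dy * np.sin(theta)
            v = -dx * np.sin(theta) + dy * np.cos(theta)
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            fg[inside] = 1
            tissue[inside] = k  # later blobs overwrite earlier ones
        frac = fg.mean()
        if _COVERAGE_RANGE[0] <= frac <= _COVERAGE_RANGE[1]:
            return fg, tissue
    raise RuntimeError(
        f"could not reach foreground coverage in {_COVERAGE_RANGE} after "
        f"{_MAX_GEOMETRY_TRIES} tries; adjust n_blobs or image size"
    )


def _background_luminance(spec: PhantomSpec, index: int, mode: str) -> np.ndarray:
    h, w = spec.height, spec.width
    if mode == "black":
        return np.zeros((h, w))
    if mode == "white":
        return np.ones((h, w))
    # textured: seeded low-frequency Gaussian random field mapped into [0.1, 0.9]
    rng = np.random.default_rng([spec.seed, index, 1])
    noise = rng.normal(size=(h, w))
    smooth = ndimage.gaussian_filter(noise, sigma=min(h, w) / 8.0)
    lo, hi = smooth.min(), smooth.max()
    return 0.1 + 0.8 * (smooth - lo) / (hi - lo)


def generate_phantom(spec: PhantomSpec, index: int) -> PhantomSample:
    """Render sample ``index`` of the family described by ``spec``.

    Deterministic for fixed ``(spec.seed, index)``. Foreground geometry,
    tissue assignment and luminance noise are drawn from streams that do not
    depend on ``background_mode``.
    """
    spec.validate()
    rng_geom = np.random.default_rng([spec.seed, index, 0])
    fg, tissue = _blob_geometry(spec, rng_geom)

    y = _background_luminance(spec, index, spec.background_mode)
    uv = np.zeros((spec.height, spec.width, 2))
    for k, (level, (u, v)) in enumerate(spec.tissue_palette[: spec.n_tissues]):
        sel = tissue == k
        y[sel] = level
        uv[sel, 0] = u
        uv[sel, 1] = v

    if spec.noise_sd > 0:
        rng_noise = np.random.default_rng([spec.seed, index, 2])
        y = y + rng_noise.normal(0.0, spec.noise_sd, size=y.shape)
    y = np.clip(y, 0.0, 1.0)

    rgb = yuv_to_rgb(YuvImage(y=y, uv=uv))
    return PhantomSample(
        rgb=rgb,
        y=y,
        uv=uv,
        foreground=fg,
        background_mode=spec.background_mode,
        spec=spec,
        index=index,
    )


def generate_dataset(spec: PhantomSpec, n: int) -> list[PhantomSample]:
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return [generate_phantom(spec, i) for i in range(n)]


def swap_background(sample: PhantomSample, mode: str) -> PhantomSample:
    """Re-render the sample's background under ``mode``; foreground unchanged."""
    if mode not in BACKGROUND_MODES:
        raise ValueError(f"unknown background mode {mode!r}; use one of {BACKGROUND_MODES}")
    if sample.spec is None or sample.index is None:
        raise ValueError("sample does not carry its generating spec; cannot re-render")
    new_spec = dataclasses.replace(sample.spec, background_mode=mode)
    return generate_phantom(new_spec, sample.index)


# --------------------------------------------------------------------- on-disk


def _spec_to_json(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["tissue_palette"] = [[lev, list(uv)] for lev, uv in spec.tissue_palette]
    return d


def _spec_from_json(d: dict) -> PhantomSpec:
    d = dict(d)
    d["tissue_palette"] = tuple(
        (float(lev), (float(u), float(v))) for lev, (u, v) in d["tissue_palette"]
    )
    return PhantomSpec(**d)


def save_dataset(samples: list[PhantomSample], root: str | Path, spec: PhantomSpec) -> None:
    """Write ``<root>/{color,gray,mask}/<index>.png`` plus ``spec.json``."""
    import imageio.v3 as iio

    root = Path(root)
    for sub in ("color", "gray", "mask"):
        (root / sub).mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(samples):
        iio.imwrite(root / "color" / f"{i}.png", np.round(s.rgb * 255).astype(np.uint8))
        iio.imwrite(root / "gray" / f"{i}.png", np.round(s.y * 255).astype(np.uint8))
        iio.imwrite(root / "mask" / f"{i}.png", (s.foreground * 255).astype(np.uint8))
    (root / "spec.json").write_text(
        json.dumps({"spec": _spec_to_json(spec), "n": len(samples)}, indent=2)
    )


def load_dataset(root: str | Path) -> list[PhantomSample]:
    """Regenerate the dataset recorded at ``root`` from its spec.json.

    The PNG files are 8-bit quantized; regenerating from the recorded spec
    restores the exact float sample (the PNGs exist for inspection and for
    external consumers).
    """
    root = Path(root)
    meta = json.loads((root / "spec.json").read_text())
    spec = _spec_from_json(meta["spec"])
    return generate_dataset(spec, int(meta["n"]))
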