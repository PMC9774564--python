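"""Collaborative training of generator, segmenter and discriminators.

Each step, with batch size 1 by default:

1. forward: chroma = G(y); the recomposed color image fc(G(y), y) is the
   luminance concatenated with the predicted chroma; the segmenter S runs
   on the recomposed image; the relaxed spatial mask Ms is sampled at the
   epoch's temperature.
2. discriminator step: D1 sees (real, fake) full images, D2 sees the
   mask-weighted pair; fake images and the mask are detached so the step
   touches no generator/segmenter parameters.
3. generator/segmenter step: non-saturating adversarial terms plus the
   color and segmentation losses, with the mask attached so gradients can
   reach the segmenter through it.

Optimization follows Adam at learning rate 1e-4, batch size 1, 10 epochs,
with loss weights lambda_col = lambda_seg = 1.0 and the linear temperature
decay from 1.0. Everything is reproducible from ``TrainConfig.seed``.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .colorspace import YuvImage, to_network_range, yuv_to_rgb
from .losses import LossWeights, gan_losses, color_loss, seg_loss, total_losses
from .metrics import evaluate as evaluate_metrics
from .networks import (
    NetworkConfig,
    PROFILES,
    make_discriminator,
    make_generator,
    make_segmenter,
)
from .nn import Adam, Tensor, concat
from .phantom import PhantomSample, load_dataset, swap_background
from .spatial_mask import MaskConfig, hard_mask, relaxed_mask, sample_gumbel, temperature_at

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "ABLATION_SETTINGS",
    "ablation_weights",
    "train",
    "colorize",
    "foreground_mae",
    "cross_background_discrepancy",
    "run_ablation",
    "save_model",
    "load_model",
]

ABLATION_SETTINGS = ("full", "wo_color", "wo_gan1", "wo_gan2")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    batch_size: int = 1
    learning_rate: float = 1e-4
    optimizer: str = "adam"
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    mask_cfg: MaskConfig = field(default_factory=MaskConfig)
    net_cfg: NetworkConfig = field(default_factory=lambda: PROFILES["desk"])
    data_root: str | None = None
    out_dir: str | None = None
    mask_stop_gradient: bool = False

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        self.weights.validate()
        self.mask_cfg.validate()
        self.net_cfg.validate()


@dataclass
class TrainedModel:
    generator: object
    segmenter: object
    d1: object | None
    d2: object | None
    cfg: TrainConfig
    log: list[dict] = field(default_factory=list)

    def colorize(self, gray: np.ndarray):
        return colorize(self, gray)


def _batchify(samples: list[PhantomSample], order: np.ndarray, batch_size: int):
    for start in range(0, len(order), batch_size):
        yield [samples[i] for i in order[start : start + batch_size]]


def _stack_batch(batch: list[PhantomSample]):
    y_net = np.stack([to_network_range(s.y)[None, :, :] for s in batch])  # (N,1,H,W)
    uv = np.stack([s.uv.transpose(2, 0, 1) for s in batch])  # (N,2,H,W)
    m = np.stack([s.foreground[None, :, :].astype(np.float64) for s in batch])
    x_real = np.concatenate([y_net, uv], axis=1)  # (N,3,H,W) in network range
    return y_net, uv, m, x_real


def train(cfg: TrainConfig, dataset: list[PhantomSample] | None = None) -> TrainedModel:
    """Train a model on phantom samples (in memory or from ``cfg.data_root``)."""
    cfg.validate()
    if dataset is None:
        if cfg.data_root is None:
            raise ValueError("either a dataset or cfg.data_root is required")
        dataset = load_dataset(cfg.data_root)
    if not dataset:
        raise ValueError("dataset is empty")

    # single precision is ample for SGD-style training and about twice as
    # fast on CPU; restored afterwards so analysis code stays float64
    from .nn.tensor import get_default_dtype, set_default_dtype

    prev_dtype = get_default_dtype()
    set_default_dtype(np.float32)
    try:
        return _train_impl(cfg, dataset)
    finally:
        set_default_dtype(prev_dtype)


def _train_impl(cfg: TrainConfig, dataset: list[PhantomSample]) -> TrainedModel:
    w = cfg.weights
    gen = make_generator(cfg.net_cfg, np.random.default_rng([cfg.seed, 1]))
    seg = make_segmenter(cfg.net_cfg, np.random.default_rng([cfg.seed, 2]))
    d1 = make_discriminator(cfg.net_cfg, np.random.default_rng([cfg.seed, 3])) if w.enable_gan1 else None
    d2 = make_discriminator(cfg.net_cfg, np.random.default_rng([cfg.seed, 4])) if w.enable_gan2 else None

    opt_g = Adam(gen.parameters() + seg.parameters(), lr=cfg.learning_rate)
    d_params = (d1.parameters() if d1 else []) + (d2.parameters() if d2 else [])
    opt_d = Adam(d_params, lr=cfg.learning_rate) if d_params else None

    shuffle_rng = np.random.default_rng([cfg.seed, 5])
    gumbel_rng = np.random.default_rng([cfg.seed, 6])

    model = TrainedModel(generator=gen, segmenter=seg, d1=d1, d2=d2, cfg=cfg)
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(
            json.dumps(dataclasses.asdict(cfg), indent=2, default=str)
        )

    step = 0
    for epoch in range(cfg.epochs):
        tau = temperature_at(epoch, cfg.epochs, cfg.mask_cfg)
        order = shuffle_rng.permutation(len(dataset))
        for batch in _batchify(dataset, order, cfg.batch_size):
            y_net, uv_true, m_true, x_real = _stack_batch(batch)
            gen.train()
            seg.train()

            # ---- forward: synthesize, segment, sample the relaxed mask
            y_t = Tensor(y_net)
            uv_hat = gen(y_t)
            x_fake = concat([y_t, uv_hat], axis=1)  # fc(G(y), y)
            p = seg(x_fake)
            p_for_mask = p.detach() if cfg.mask_stop_gradient else p
            noise_shape = p.shape
            g1 = sample_gumbel(noise_shape, gumbel_rng)
            g0 = sample_gumbel(noise_shape, gumbel_rng)
            mask = relaxed_mask(p_for_mask, tau, g1, g0)

            # ---- discriminator step (fakes and mask detached)
            gan1_d_val = gan2_d_val = 0.0
            if opt_d is not None:
                d_terms = []
                if d1 is not None:
                    d1.train()
                    d1_real = d1(Tensor(x_real))
                    d1_fake = d1(x_fake.detach())
                    gan1_d, _ = gan_losses(d1_real, d1_fake)
                    gan1_d_val = gan1_d.item()
                    d_terms.append(gan1_d)
                if d2 is not None:
                    d2.train()
                    mask_det = Tensor(mask.values.data)
                    d2_real = d2(Tensor(x_real) * mask_det)
                    d2_fake = d2(x_fake.detach() * mask_det)
                    gan2_d, _ = gan_losses(d2_real, d2_fake)
                    gan2_d_val = gan2_d.item()
                    d_terms.append(gan2_d)
                loss_d = d_terms[0] if len(d_terms) == 1 else d_terms[0] + d_terms[1]
                opt_d.zero_grad()
                loss_d.backward()
                opt_d.step()

            # ---- generator/segmenter step
            gan1_g = Tensor(0.0)
            if d1 is not None:
                _, gan1_g = gan_losses(Tensor(0.5), d1(x_fake))
            gan2_g = Tensor(0.0)
            if d2 is not None:
                x_fake_masked = x_fake * mask.values
                _, gan2_g = gan_losses(Tensor(0.5), d2(x_fake_masked))
            col = color_loss(uv_hat, Tensor(uv_true), mask) if w.enable_color else Tensor(0.0)
            sl = seg_loss(p, m_true)

            total_g, _, bundle = total_losses(
                w,
                color=col,
                gan1_d=gan1_d_val,
                gan1_g=gan1_g,
                gan2_d=gan2_d_val,
                gan2_g=gan2_g,
                seg=sl,
            )
            opt_g.zero_grad()
            total_g.backward()
            opt_g.step()

            model.log.append(
                {
                    "step": step,
                    "epoch": epoch,
                    "tau": tau,
                    **dataclasses.asdict(bundle),
                }
            )
            step += 1

        if out_dir:
            save_model(model, out_dir / f"checkpoint_{epoch}.npz")

    if out_dir:
        with open(out_dir / "training_log.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(model.log[0].keys()))
            writer.writeheader()
            writer.writerows(model.log)
    return model


def colorize(model: TrainedModel, gray: np.ndarray):
    """Colorize a single-channel image in [0, 1].

    Returns ``(rgb, mask)``: the recomposed RGB image (luminance passed
    through unchanged, chroma predicted) and the hard foreground mask from
    the segmenter applied to the recomposed image.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError(f"expected a single-channel (H, W) image, got shape {gray.shape}")
    model.generator.eval()
    model.segmenter.eval()
    y_net = to_network_range(gray)[None, None, :, :]
    y_t = Tensor(y_net)
    uv_hat = model.generator(y_t)
    x_fake = concat([y_t, uv_hat], axis=1)
    p = model.segmenter(x_fake)
    uv_img = uv_hat.data[0].transpose(1, 2, 0)
    rgb = yuv_to_rgb(YuvImage(y=gray, uv=uv_img))
    mask = hard_mask(p.data[0, 0], model.cfg.mask_cfg.threshold)
    return rgb, mask


def foreground_mae(colorizer, samples: list[PhantomSample]) -> float:
    """MAE between prediction and ground truth restricted to foreground pixels."""
    fn = getattr(colorizer, "colorize", colorizer)
    errs = []
    for s in samples:
        out = fn(s.y)
        rgb = out[0] if isinstance(out, tuple) else out
        fg = s.foreground.astype(bool)
        errs.append(float(np.abs(rgb[fg] - s.rgb[fg]).mean()))
    return float(np.mean(errs))


def cross_background_discrepancy(colorizer, samples: list[PhantomSample]) -> float:
    """Foreground MAE between colorizations of the same phantom rendered on
    black vs white backgrounds; low values mean background-invariant output."""
    fn = getattr(colorizer, "colorize", colorizer)
    diffs = []
    for s in samples:
        s_black = swap_background(s, "black")
        s_white = swap_background(s, "white")
        out_b = fn(s_black.y)
        out_w = fn(s_white.y)
        rgb_b = out_b[0] if isinstance(out_b, tuple) else out_b
        rgb_w = out_w[0] if isinstance(out_w, tuple) else out_w
        fg = s.foreground.astype(bool)
        diffs.append(float(np.abs(rgb_b[fg] - rgb_w[fg]).mean()))
    return float(np.mean(diffs))


def ablation_weights(setting: str, base: LossWeights = LossWeights()) -> LossWeights:
    if setting not in ABLATION_SETTINGS:
        raise ValueError(f"unknown ablation setting {setting!r}; use one of {ABLATION_SETTINGS}")
    return dataclasses.replace(
        base,
        enable_color=base.enable_color and setting != "wo_color",
        enable_gan1=base.enable_gan1 and setting != "wo_gan1",
        enable_gan2=base.enable_gan2 and setting != "wo_gan2",
    )


def run_ablation(
    cfg: TrainConfig,
    train_data: list[PhantomSample],
    test_data: list[PhantomSample],
    settings: tuple[str, ...] = ABLATION_SETTINGS,
    seeds: tuple[int, ...] = (0, 1, 2),
) -> pd.DataFrame:
    """Train one model per (setting, seed) on identical data and evaluate on
    held-out phantoms under each background condition."""
    rows = []
    for setting in settings:
        for seed in seeds:
            run_cfg = dataclasses.replace(
                cfg, seed=seed, weights=ablation_weights(setting, cfg.weights), out_dir=None
            )
            model = train(run_cfg, train_data)
            report = evaluate_metrics(model, test_data)
            avg = report[report["condition"] == "Average"].iloc[0]
            rows.append(
                {
                    "setting": setting,
                    "seed": seed,
                    "mae": float(avg["mae"]),
                    "psnr": float(avg["psnr"]),
                    "ssim": float(avg["ssim"]),
                    "fg_mae": foreground_mae(model, test_data),
                    "cross_bg": cross_background_discrepancy(model, test_data),
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ checkpoints


def save_model(model: TrainedModel, path: str | Path) -> None:
    arrays: dict[str, np.ndarray] = {}
    for prefix, mod in (
        ("gen", model.generator),
        ("seg", model.segmenter),
        ("d1", model.d1),
        ("d2", model.d2),
    ):
        if mod is None:
            continue
        for name, arr in mod.state_dict().items():
            arrays[f"{prefix}.{name}"] = arr
    arrays["__config__"] = np.frombuffer(
        json.dumps(dataclasses.asdict(model.cfg), default=str).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path: str | Path) -> TrainedModel:
    data = np.load(path)
    cfg_dict = json.loads(bytes(data["__config__"]).decode())
    cfg = TrainConfig(
        epochs=int(cfg_dict["epochs"]),
        batch_size=int(cfg_dict["batch_size"]),
        learning_rate=float(cfg_dict["learning_rate"]),
        seed=int(cfg_dict["seed"]),
        weights=LossWeights(**cfg_dict["weights"]),
        mask_cfg=MaskConfig(**cfg_dict["mask_cfg"]),
        net_cfg=NetworkConfig(**cfg_dict["net_cfg"]),
        mask_stop_gradient=bool(cfg_dict.get("mask_stop_gradient", False)),
    )
    rng = np.random.default_rng(0)
    gen = make_generator(cfg.net_cfg, rng)
    seg = make_segmenter(cfg.net_cfg, rng)
    d1 = make_discriminator(cfg.net_cfg, rng) if cfg.weights.enable_gan1 else None
    d2 = make_discriminator(cfg.net_cfg, rng) if cfg.weights.enable_gan2 else None
    model = TrainedModel(generator=gen, segmenter=seg, d1=d1, d2=d2, cfg=cfg)
    for prefix, mod in (("gen", gen), ("seg", seg), ("d1", d1), ("d2", d2)):
        if mod is None:
            continue
        state = {
            key[len(prefix) + 1 :]: data[key]
            for key in data.files
            if key.startswith(prefix + ".")
        }
        if state:
            mod.load_state_dict(state)
    return model
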