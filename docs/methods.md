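# Methods

## Model and assumptions

Colorization is treated as pixel-wise regression in YUV: the luminance
channel is the observed grayscale image, and the model predicts the two
chroma channels, which are recomposed with the input luminance into a color
image. The assumptions this encodes:

* luminance is preserved exactly — the model never alters intensity, only
  adds chroma;
* tissue chroma is predictable from intensity and local context (true of
  stained/photographic cross-sections to a useful approximation, not of
  arbitrary natural images);
* background content is nuisance: the mapping should not depend on it.

The third assumption is operationalized by an auxiliary segmentation
branch. A U-Net predicts a per-pixel foreground probability from the
recomposed color image; a spatial mask derived from it weights both the
color loss and the input of a second discriminator, so adversarial pressure
concentrates on tissue. At inference the mask is the hard indicator
`1{p >= 0.5}` (boundary inclusive); during training it is relaxed with the
Gumbel-softmax trick so gradients flow. For a two-class mask the relaxation
reduces to `sigmoid(((log p − log(1−p)) + (g1 − g0)) / τ)`, which is the
numerically stable form we compute; probabilities are clipped to
`[1e−6, 1 − 1e−6]` before the logs. One Gumbel noise field is drawn per
training step and shared between the real-image and fake-image mask
applications, since the same mask weights both critic inputs.

Gradients are allowed to flow from the mask back into the segmenter (and
through the recomposed image into the generator); a `mask_stop_gradient`
flag detaches them if wanted. The segmenter is always trained on the
*synthesized* image, not the ground-truth color image — its cross-entropy
target is the exact foreground map.

## Losses

* Color: `mean|Δuv| + mean|Δuv ⊙ M_s|`, the mask broadcast across both
  chroma channels. Both terms are means over all pixels and channels.
* Adversarial (both critics): the discriminator minimizes
  `−[log D(real) + log(1 − D(fake))]`; the generator minimizes the
  non-saturating `−log D(fake)`. Scores are clipped to `[1e−7, 1 − 1e−7]`.
  Real/fake targets are not label-smoothed.
* Segmentation: mean binary cross-entropy.
* Totals: generator/segmenter side `gan1_g + gan2_g + λ_col·color +
  λ_seg·seg` with `λ_col = λ_seg = 1`; discriminator side the sum of the
  enabled `d` terms. Disabling all of color/gan1/gan2 is rejected as a
  degenerate objective. Each step runs one discriminator update (fakes and
  mask detached) followed by one generator/segmenter update.

## Parameters that matter

| parameter | default | meaning |
| --- | --- | --- |
| learning rate | 1e−4 | Adam, β = (0.9, 0.999); one shared value for all networks |
| batch size | 1 | batch-norm statistics are then per-image; see below |
| epochs | 10 | temperature schedule is tied to this |
| τ schedule | max(1·(1 − t/t_max), 0.1) | linear decay per epoch, floored so the softmax never divides by zero |
| mask threshold | 0.5 | hard-mask boundary, inclusive |
| λ_col, λ_seg | 1.0, 1.0 | loss weights |
| base_channels | desk 6 / full 32 | width multiplier for all three networks |
| n_downsample | desk 1 / full 2 | stride-2 stages in the generator encoder |

The `desk` profile (64 px, base 6, one stride-2 stage) scales the 256-px
architecture proportionally: one halving at 64 px gives the residual blocks
the same relative receptive field as two halvings at 256 px, and keeps a
full training run in minutes on one CPU. The `full` profile preserves the
full-scale topology at 256 px but is not exercised by the tests.

## The autodiff engine

No autodiff framework is part of this package's dependency set, so
`maskcolor.nn` implements reverse-mode differentiation over numpy arrays:
broadcasting arithmetic, exp/log/tanh/sigmoid/relu/abs/pow/clip,
axis reductions, 2-D matmul, im2col convolution with stride and padding,
nearest-neighbour upsampling, concatenation, and a fused batch-norm
primitive with a hand-written backward. Every primitive and the composed
networks are validated against central finite differences (relative error
< 1e−4 on 8×8 inputs; the engine defaults to float64 so these checks are
well conditioned). Training switches the engine to float32 for speed and
restores float64 afterwards.

Batch norm at batch size 1 normalizes per image. A `population_stats`
variant (normalize by running statistics, treated as constants) is
available; measured on the phantom task it did not outperform standard
batch statistics, so the standard form is the default.

## The phantom generator

Each phantom is a large elliptical "body" cross-section with organ-sized
elliptical structures painted over it (later blobs win), on a background
that is black, white, or a seeded low-frequency gray texture. Tissues take
their luminance level and chroma from a fixed palette whose levels differ
by at least 0.05, so chroma is a deterministic function of quantized
luminance inside the foreground and a perfect colorizer exists by
construction. Gaussian noise (default σ = 0.01, luminance only) emulates
sensor noise without corrupting the chroma targets. All randomness is keyed
by `(seed, index, stream)`, with the geometry and noise streams independent
of the background mode — so swapping a sample's background changes nothing
inside the foreground, bit for bit. Foreground coverage is rejection-sampled
into [0.10, 0.80].

What the phantoms do **not** emulate: anti-aliased tissue boundaries,
texture within a tissue, luminance ambiguity between foreground and
background (the textured mode overlaps tissue luminance levels and is the
hard case), imaging physics, or annotation noise in the foreground maps.
Passing tests therefore demonstrate the mechanics of the method — mask
relaxation, background-invariant masked critics, trainability — not
clinical-grade colorization.

## Evaluation

MAE, PSNR (capped at 100 dB for identical images) and SSIM (11×11 Gaussian
window, σ = 1.5, K1 = 0.01, K2 = 0.03, population covariance, dynamic range
1.0) are computed on recomposed RGB in [0, 1], aggregated per background
condition with an unweighted Average row. MAE can alternatively be computed
on the chroma channels (`mae_space="uv"`). Two method-specific quantities:
*foreground MAE* (error restricted to tissue pixels) and *cross-background
discrepancy* (foreground MAE between colorizations of the same phantom
rendered on black vs white backgrounds — zero for a perfectly
background-invariant model).

## Problem sizes and measured behaviour

The shipped experiments use: desk training 64×64 with 200 training and 50
held-out phantoms for 10 epochs; the loss ablation 32×32 with 60 training
and 12 held-out phantoms (evaluated on black and white backgrounds) for 10
epochs, three seeds per setting, medians reported.

Two caveats the tests make explicit rather than hide:

* The color-only configuration converges to a held-out foreground MAE of
  roughly 0.08 at desk scale, not arbitrarily low. Adam's per-parameter
  step is ≈ the learning rate, so 2 000 steps at 1e−4 bound total parameter
  movement; single-image overfitting at larger budgets reaches ≈ 0.015, so
  the limit is the optimization budget, not the architecture or the task.
* At desk budgets the discriminators are far from convergence and their
  generator terms behave as noise on the chroma regression: dropping the
  masked critic (`wo_gan2`) *improves* micro-scale MAE and cross-background
  discrepancy, the opposite of the fully-trained ordering. Dropping the
  color loss degrades accuracy at every scale we measured, consistently
  with its role as the regression anchor. The background-invariance
  mechanism itself — bit-identical masked critic inputs under background
  swaps — holds exactly and is tested directly.

## Degenerate inputs and numerical choices

* Probabilities/scores are clipped before any log; clip gradients pass
  through the interior and vanish outside.
* Out-of-gamut YUV→RGB results are clipped to [0, 1]; the RGB↔YUV matrices
  are exact inverses of each other (BT.601 full-range, chroma rescaled to
  [−1, 1] by U/V half-ranges 0.436/0.615).
* Non-finite loss values abort training immediately, naming the offending
  term.
* PNG I/O quantizes to 8 bits; `load_dataset` regenerates exact float
  samples from the recorded spec instead of re-reading quantized pixels.
* Checkpoints are `.npz` archives of all parameters and batch-norm running
  statistics plus the embedded config.

## Known limitations

Single-channel batch norm statistics at batch 1, nearest-neighbour
upsampling (no learned transposed convolutions), no learning-rate schedule,
no label smoothing or gradient penalties, CPU-scale widths only, and the
phantom simplifications listed above. The 256-px profile is provided but
untested end to end.
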