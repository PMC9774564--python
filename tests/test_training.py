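import dataclasses

import numpy as np
import pytest

from maskcolor.colorspace import rgb_to_yuv
from maskcolor.losses import LossWeights, gan_losses
from maskcolor.networks import make_discriminator, make_generator, make_segmenter
from maskcolor.nn import Adam, Tensor, param_checksum
from maskcolor.spatial_mask import temperature_at
from maskcolor.training import (
    TrainConfig,
    ablation_weights,
    colorize,
    cross_background_discrepancy,
    foreground_mae,
    load_model,
    run_ablation,
    save_model,
    train,
)


@pytest.fixture
def tiny_cfg(tiny_net_cfg):
    return TrainConfig(epochs=2, seed=3, net_cfg=tiny_net_cfg)


class TestTrain:
    def test_identical_seeds_give_identical_loss_logs(self, tiny_cfg, tiny_samples):
        log_a = train(tiny_cfg, tiny_samples).log
        log_b = train(tiny_cfg, tiny_samples).log
        assert log_a == log_b

    def test_different_seeds_diverge(self, tiny_cfg, tiny_samples):
        log_a = train(tiny_cfg, tiny_samples).log
        log_b = train(dataclasses.replace(tiny_cfg, seed=4), tiny_samples).log
        assert log_a != log_b

    def test_logged_temperature_follows_schedule(self, tiny_cfg, tiny_samples):
        model = train(tiny_cfg, tiny_samples)
        for row in model.log:
            expected = temperature_at(row["epoch"], tiny_cfg.epochs, tiny_cfg.mask_cfg)
            assert row["tau"] == expected

    def test_all_logged_losses_finite(self, tiny_cfg, tiny_samples):
        model = train(tiny_cfg, tiny_samples)
        for row in model.log:
            for key, value in row.items():
                assert np.isfinite(value), key

    def test_empty_dataset_rejected(self, tiny_cfg):
        with pytest.raises(ValueError, match="empty"):
            train(tiny_cfg, [])

    def test_invalid_config_rejected(self, tiny_cfg, tiny_samples):
        with pytest.raises(ValueError, match="epochs"):
            train(dataclasses.replace(tiny_cfg, epochs=0), tiny_samples)

    def test_checkpoints_and_logs_written(self, tiny_cfg, tiny_samples, tmp_path):
        cfg = dataclasses.replace(tiny_cfg, out_dir=str(tmp_path / "run"))
        train(cfg, tiny_samples)
        out = tmp_path / "run"
        assert (out / "config.json").exists()
        assert (out / "training_log.csv").exists()
        assert (out / "checkpoint_0.npz").exists()
        assert (out / "checkpoint_1.npz").exists()


class TestAblationWiring:
    def test_disabled_discriminators_never_constructed(self, tiny_cfg, tiny_samples):
        w = LossWeights(enable_gan2=False)
        model = train(dataclasses.replace(tiny_cfg, weights=w), tiny_samples)
        assert model.d2 is None and model.d1 is not None
        assert all(row["gan2_g"] == 0.0 for row in model.log)

        w = LossWeights(enable_gan1=False)
        model = train(dataclasses.replace(tiny_cfg, weights=w), tiny_samples)
        assert model.d1 is None and model.d2 is not None

    def test_ablation_weight_settings(self):
        assert not ablation_weights("wo_color").enable_color
        assert not ablation_weights("wo_gan1").enable_gan1
        assert not ablation_weights("wo_gan2").enable_gan2
        full = ablation_weights("full")
        assert full.enable_color and full.enable_gan1 and full.enable_gan2
        with pytest.raises(ValueError, match="setting"):
            ablation_weights("wo_everything")

    def test_run_ablation_produces_one_row_per_setting_and_seed(
        self, tiny_cfg, tiny_samples
    ):
        cfg = dataclasses.replace(tiny_cfg, epochs=1)
        report = run_ablation(
            cfg, tiny_samples[:2], tiny_samples[2:], settings=("full", "wo_color"), seeds=(0, 1)
        )
        assert len(report) == 4
        assert set(report["setting"]) == {"full", "wo_color"}
        assert {"mae", "psnr", "ssim", "fg_mae", "cross_bg"} <= set(report.columns)


class TestParameterIsolation:
    def test_discriminator_step_leaves_generator_untouched(self, tiny_net_cfg, tiny_samples):
        """Replicates one adversarial update: only D parameters may move."""
        rng = np.random.default_rng
        gen = make_generator(tiny_net_cfg, rng(1))
        seg = make_segmenter(tiny_net_cfg, rng(2))
        d1 = make_discriminator(tiny_net_cfg, rng(3))
        opt_d = Adam(d1.parameters(), lr=1e-3)

        s = tiny_samples[0]
        y = Tensor((2 * s.y - 1)[None, None])
        from maskcolor.nn import concat

        x_fake = concat([y, gen(y)], axis=1)
        g_sum, s_sum, d_sum = param_checksum(gen), param_checksum(seg), param_checksum(d1)
        d_loss, _ = gan_losses(d1(x_fake.detach()), d1(x_fake.detach()))
        opt_d.zero_grad()
        d_loss.backward()
        opt_d.step()
        assert param_checksum(gen) == g_sum
        assert param_checksum(seg) == s_sum
        assert param_checksum(d1) != d_sum

    def test_generator_step_leaves_discriminator_untouched(self, tiny_cfg, tiny_samples):
        model = train(tiny_cfg, tiny_samples)
        # after joint training both sides have moved; freeze D and verify a
        # further G-only optimizer cannot change it
        d_sum = param_checksum(model.d1)
        opt_g = Adam(model.generator.parameters(), lr=1e-3)
        s = tiny_samples[0]
        pred = model.generator(Tensor((2 * s.y - 1)[None, None]))
        loss = pred.abs().mean()
        opt_g.zero_grad()
        loss.backward()
        opt_g.step()
        assert param_checksum(model.d1) == d_sum


class TestColorize:
    def test_luminance_passes_through_unchanged(self, tiny_cfg, tiny_samples):
        # fc only concatenates the predicted chroma onto the input
        # luminance, so wherever the output round-trips inside the RGB
        # gamut the recovered luminance equals the input exactly
        model = train(tiny_cfg, tiny_samples)
        s = tiny_samples[0]
        rgb, _ = colorize(model, s.y)

        model.generator.eval()
        uv = model.generator(Tensor((2 * s.y - 1)[None, None])).data[0].transpose(1, 2, 0)
        from maskcolor.colorspace import U_MAX, V_MAX, _YUV_TO_RGB

        yuv = np.concatenate([s.y[..., None], uv * np.array([U_MAX, V_MAX])], axis=-1)
        unclipped = yuv @ _YUV_TO_RGB.T
        in_gamut = ((unclipped >= 0.0) & (unclipped <= 1.0)).all(axis=-1)
        assert in_gamut.mean() > 0.2  # a nontrivial share round-trips cleanly
        assert np.abs(rgb_to_yuv(rgb).y - s.y)[in_gamut].max() < 1e-9

    def test_deterministic_and_in_range(self, tiny_cfg, tiny_samples):
        model = train(tiny_cfg, tiny_samples)
        a, mask_a = colorize(model, tiny_samples[1].y)
        b, mask_b = colorize(model, tiny_samples[1].y)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(mask_a.values, mask_b.values)
        assert a.min() >= 0.0 and a.max() <= 1.0
        assert set(np.unique(mask_a.values)) <= {0.0, 1.0}

    def test_multichannel_input_rejected(self, tiny_cfg, tiny_samples):
        model = train(tiny_cfg, tiny_samples)
        with pytest.raises(ValueError, match="single-channel"):
            colorize(model, np.zeros((8, 8, 3)))


class TestEvaluationHelpers:
    def test_oracle_has_zero_foreground_mae_and_discrepancy(self, tiny_samples):
        lookup = {s.y.tobytes(): s.rgb for s in tiny_samples}
        from maskcolor.phantom import swap_background

        extended = dict(lookup)
        for s in tiny_samples:
            for mode in ("black", "white"):
                sw = swap_background(s, mode)
                extended[sw.y.tobytes()] = sw.rgb
        oracle = lambda gray: extended[gray.tobytes()]
        assert foreground_mae(oracle, tiny_samples) == 0.0
        assert cross_background_discrepancy(oracle, tiny_samples) == 0.0


class TestCheckpointRoundTrip:
    def test_saved_model_reproduces_outputs(self, tiny_cfg, tiny_samples, tmp_path):
        model = train(tiny_cfg, tiny_samples)
        path = tmp_path / "ckpt.npz"
        save_model(model, path)
        restored = load_model(path)
        a, _ = colorize(model, tiny_samples[0].y)
        b, _ = colorize(restored, tiny_samples[0].y)
        np.testing.assert_array_equal(a, b)
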