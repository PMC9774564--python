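import dataclasses

import numpy as np
import pytest

from maskcolor.colorspace import rgb_to_yuv
from maskcolor.phantom import (
    BACKGROUND_MODES,
    DEFAULT_PALETTE,
    PhantomSpec,
    generate_dataset,
    generate_phantom,
    load_dataset,
    save_dataset,
    swap_background,
)

SPEC = PhantomSpec(seed=7)


class TestGeneratePhantom:
    def test_bit_identical_regeneration(self):
        a = generate_phantom(SPEC, 0)
        b = generate_phantom(SPEC, 0)
        for field in ("rgb", "y", "uv", "foreground"):
            np.testing.assert_array_equal(getattr(a, field), getattr(b, field))

    def test_black_background_pixels_are_zero_without_noise(self):
        spec = dataclasses.replace(SPEC, noise_sd=0.0)
        s = generate_phantom(spec, 3)
        bg = s.foreground == 0
        assert bg.any()
        np.testing.assert_array_equal(s.rgb[bg], 0.0)
        np.testing.assert_array_equal(s.y[bg], 0.0)

    @pytest.mark.parametrize("mode", BACKGROUND_MODES)
    def test_background_modes_share_foreground_exactly(self, mode):
        base = generate_phantom(SPEC, 1)
        other = generate_phantom(dataclasses.replace(SPEC, background_mode=mode), 1)
        np.testing.assert_array_equal(base.foreground, other.foreground)
        fg = base.foreground.astype(bool)
        np.testing.assert_array_equal(base.rgb[fg], other.rgb[fg])

    def test_chroma_is_function_of_luminance_in_foreground(self):
        # with zero noise the phantom task has an exact colorizer:
        # luminance level -> palette chroma
        spec = dataclasses.replace(SPEC, noise_sd=0.0)
        lookup = {lev: np.array(uv) for lev, uv in DEFAULT_PALETTE}
        for i in range(3):
            s = generate_phantom(spec, i)
            fg = s.foreground.astype(bool)
            for lev, uv in lookup.items():
                sel = fg & np.isclose(s.y, lev)
                if sel.any():
                    expected = np.broadcast_to(uv, s.uv[sel].shape)
                    np.testing.assert_allclose(s.uv[sel], expected, atol=1e-12)

    def test_rgb_consistent_with_colorspace_conversion(self):
        s = generate_phantom(SPEC, 2)
        back = rgb_to_yuv(s.rgb)
        np.testing.assert_allclose(back.y, s.y, atol=1e-9)
        np.testing.assert_allclose(back.uv, s.uv, atol=1e-9)


class TestSpecValidation:
    def test_palette_luminance_collision_names_field(self):
        palette = ((0.40, (0.1, 0.1)), (0.42, (-0.1, 0.2)))
        spec = dataclasses.replace(SPEC, tissue_palette=palette, n_tissues=2)
        with pytest.raises(ValueError, match="tissue_palette"):
            generate_phantom(spec, 0)

    def test_zero_blobs_rejected(self):
        with pytest.raises(ValueError, match="n_blobs"):
            generate_phantom(dataclasses.replace(SPEC, n_blobs=0), 0)

    def test_bad_background_mode_rejected(self):
        with pytest.raises(ValueError, match="background_mode"):
            generate_phantom(dataclasses.replace(SPEC, background_mode="plaid"), 0)

    def test_excess_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            generate_phantom(dataclasses.replace(SPEC, noise_sd=0.5), 0)


class TestGenerateDataset:
    def test_dataset_is_deterministic_and_in_coverage_range(self):
        data = generate_dataset(SPEC, 10)
        again = generate_dataset(SPEC, 10)
        assert len(data) == 10
        for a, b in zip(data, again):
            np.testing.assert_array_equal(a.rgb, b.rgb)
            assert 0.10 <= a.foreground_fraction <= 0.80

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError, match="n"):
            generate_dataset(SPEC, 0)


class TestSwapBackground:
    def test_swap_preserves_foreground_for_all_mode_pairs(self):
        s = generate_phantom(SPEC, 5)
        fg = s.foreground.astype(bool)
        for mode in BACKGROUND_MODES:
            swapped = swap_background(s, mode)
            assert swapped.background_mode == mode
            np.testing.assert_array_equal(swapped.foreground, s.foreground)
            np.testing.assert_array_equal(swapped.rgb[fg], s.rgb[fg])
            np.testing.assert_array_equal(swapped.y[fg], s.y[fg])

    def test_swap_to_same_mode_is_identity(self):
        s = generate_phantom(SPEC, 5)
        same = swap_background(s, s.background_mode)
        np.testing.assert_array_equal(same.rgb, s.rgb)

    def test_black_to_white_moves_background_luminance(self):
        spec = dataclasses.replace(SPEC, noise_sd=0.0)
        s = generate_phantom(spec, 4)
        w = swap_background(s, "white")
        bg = s.foreground == 0
        np.testing.assert_array_equal(s.y[bg], 0.0)
        np.testing.assert_array_equal(w.y[bg], 1.0)
        fg = ~bg
        assert np.abs(s.rgb[fg] - w.rgb[fg]).max() == 0.0

    def test_masked_image_invariant_under_swap(self):
        s = generate_phantom(SPEC, 6)
        masked = s.rgb * s.foreground[..., None]
        for mode in BACKGROUND_MODES:
            sw = swap_background(s, mode)
            np.testing.assert_array_equal(sw.rgb * sw.foreground[..., None], masked)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            swap_background(generate_phantom(SPEC, 0), "chartreuse")


class TestDiskLayout:
    def test_save_load_round_trip_and_byte_stability(self, tmp_path):
        spec = dataclasses.replace(SPEC, height=16, width=16, n_blobs=2)
        data = generate_dataset(spec, 3)
        root = tmp_path / "ds"
        save_dataset(data, root, spec)
        for sub in ("color", "gray", "mask"):
            assert sorted(p.name for p in (root / sub).iterdir()) == [
                "0.png",
                "1.png",
                "2.png",
            ]
        reloaded = load_dataset(root)
        assert len(reloaded) == 3
        for a, b in zip(data, reloaded):
            np.testing.assert_array_equal(a.rgb, b.rgb)

        first = (root / "color" / "0.png").read_bytes()
        save_dataset(data, tmp_path / "ds2", spec)
        assert (tmp_path / "ds2" / "color" / "0.png").read_bytes() == first

    def test_mask_png_is_binary(self, tmp_path):
        import imageio.v3 as iio

        spec = dataclasses.replace(SPEC, height=16, width=16, n_blobs=2)
        save_dataset(generate_dataset(spec, 1), tmp_path / "d", spec)
        mask = iio.imread(tmp_path / "d" / "mask" / "0.png")
        assert set(np.unique(mask)) <= {0, 255}
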