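"""Decoding, illuminant estimation/compensation, denoising, HSL conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

import sclerascan as ss
from sclerascan.colorimetry import IlluminantGains, linear_to_srgb, srgb_to_linear
from sclerascan.errors import (
    DegenerateInputError,
    ImageFormatError,
    ImageReadError,
    ParameterError,
)

from conftest import cast_in_linear


class TestReadImage:
    def test_png_roundtrip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(0)
        arr = rng.integers(0, 256, (2, 2, 3)).astype(np.uint8)
        p = tmp_path / "t.png"
        Image.fromarray(arr).save(p)
        assert np.array_equal(ss.read_image(p), arr)

    def test_jpeg_q95_within_4_counts_on_smooth_content(self, tmp_path, smooth_image):
        p = tmp_path / "t.jpg"
        Image.fromarray(smooth_image).save(p, quality=95)
        back = ss.read_image(p)
        assert np.abs(back.astype(int) - smooth_image.astype(int)).max() <= 4

    def test_text_file_raises_format_error(self, tmp_path):
        p = tmp_path / "not_an_image.txt"
        p.write_text("definitely not pixels")
        with pytest.raises(ImageFormatError):
            ss.read_image(p)

    def test_missing_file_raises_with_path(self, tmp_path):
        with pytest.raises(ImageReadError, match="nope.png"):
            ss.read_image(tmp_path / "nope.png")

    def test_exif_orientation_applied(self, tmp_path):
        arr = np.zeros((10, 20, 3), np.uint8)
        arr[0, :, :] = 255  # white top row
        im = Image.fromarray(arr)
        exif = im.getexif()
        exif[0x0112] = 3  # rotated 180 degrees
        p = tmp_path / "e.jpg"
        im.save(p, exif=exif, quality=100)
        back = ss.read_image(p)
        assert back[-1].mean() > 200 and back[0].mean() < 50

    def test_grayscale_raises_format_error(self, tmp_path):
        p = tmp_path / "g.png"
        Image.fromarray(np.zeros((5, 5), np.uint8)).save(p)
        with pytest.raises(ImageFormatError):
            ss.read_image(p)


class TestIlluminantEstimation:
    def test_balanced_gray_gives_unit_gains(self):
        img = np.full((8, 8, 3), 128, np.uint8)
        for method in ("gray_world", "shades_of_gray"):
            g = ss.estimate_illuminant(img, method=method)
            assert np.allclose(g.gains, 1.0, atol=1e-9)

    def test_gray_world_recovers_known_cast(self, gray_ramp):
        cast = cast_in_linear(gray_ramp, (2.0, 1.0, 0.5))
        g = ss.estimate_illuminant(cast, method="gray_world")
        # (0.5, 1, 2) already has geometric mean 1
        assert np.allclose(g.gains, [0.5, 1.0, 2.0], rtol=0.01)

    def test_gains_geometric_mean_is_one(self, scene):
        g = ss.estimate_illuminant(scene.image)
        assert np.prod(g.gains) == pytest.approx(1.0, abs=1e-12)

    def test_all_black_image_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            ss.estimate_illuminant(np.zeros((4, 4, 3), np.uint8))

    def test_bad_minkowski_p_rejected(self, gray_ramp):
        with pytest.raises(ParameterError):
            ss.estimate_illuminant(gray_ramp, minkowski_p=0.5)


class TestCompensation:
    def test_identity_gains_change_nothing(self, smooth_image):
        out = ss.compensate_illumination(smooth_image, IlluminantGains.identity())
        assert np.abs(out.astype(int) - smooth_image.astype(int)).max() <= 1

    @pytest.mark.parametrize("method", ["gray_world", "shades_of_gray"])
    def test_cast_then_correct_recovers_achromatic_mean_scene(self, gray_ramp, method):
        # a geometric-mean-1 cast: overall intensity is not an estimable
        # quantity under the canonical (gmean-1) gain normalization
        cast = cast_in_linear(gray_ramp, (1.3, 1.0, 1 / 1.3))
        g = ss.estimate_illuminant(cast, method=method)
        rec = ss.compensate_illumination(cast, g)
        assert np.abs(rec.astype(int) - gray_ramp.astype(int)).max() <= 2

    def test_saturated_white_clips_without_overflow(self):
        img = np.full((4, 4, 3), 255, np.uint8)
        out = ss.compensate_illumination(img, IlluminantGains(np.array([1.5, 1.0, 1.0])))
        assert out.dtype == np.uint8 and out.max() == 255

    def test_dimensions_preserved(self, scene):
        g = ss.estimate_illuminant(scene.image)
        assert ss.compensate_illumination(scene.image, g).shape == scene.image.shape

    def test_srgb_transfer_functions_invert(self):
        u = np.linspace(0, 1, 1001)
        assert np.allclose(linear_to_srgb(srgb_to_linear(u)), u, atol=1e-12)


class TestDenoise:
    def test_kernel_one_is_identity(self, smooth_image):
        assert np.array_equal(ss.denoise(smooth_image, 1), smooth_image)

    def test_uniform_image_unchanged(self):
        img = np.full((10, 10, 3), 77, np.uint8)
        assert np.array_equal(ss.denoise(img, 3), img)

    def test_salt_pixel_removed(self):
        img = np.full((9, 9, 3), 100, np.uint8)
        img[4, 4] = 255
        out = ss.denoise(img, 3)
        assert tuple(out[4, 4]) == (100, 100, 100)

    def test_even_kernel_rejected(self, smooth_image):
        with pytest.raises(ParameterError):
            ss.denoise(smooth_image, 4)

    def test_dimensions_preserved(self, scene):
        assert ss.denoise(scene.image, 5).shape == scene.image.shape


PRIMARIES = [
    ((255, 0, 0), 0.0),
    ((255, 255, 0), 60.0),  # yellow — the scleral-icterus end of the hue circle
    ((0, 255, 0), 120.0),
    ((0, 255, 255), 180.0),
    ((0, 0, 255), 240.0),
    ((255, 0, 255), 300.0),
]


class TestRgbToHsl:
    @pytest.mark.parametrize("rgb,hue", PRIMARIES)
    def test_pure_corner_hues_exact(self, rgb, hue):
        h = ss.rgb_to_hsl(np.array([[rgb]], np.uint8))
        assert h.hue[0, 0] == hue
        assert h.saturation[0, 0] == 1.0
        assert h.lightness[0, 0] == 0.5

    def test_mid_gray_is_achromatic(self):
        h = ss.rgb_to_hsl(np.array([[[128, 128, 128]]], np.uint8))
        assert not h.chromatic_mask[0, 0]
        assert h.saturation[0, 0] == 0.0
        assert h.lightness[0, 0] == pytest.approx(0.502, abs=1e-3)

    def test_chromatic_mask_matches_zero_saturation(self, scene):
        h = ss.rgb_to_hsl(scene.image)
        assert np.array_equal(h.chromatic_mask, h.saturation > 0)
        # partition: chromatic + achromatic covers every pixel exactly once
        assert h.chromatic_mask.sum() + (~h.chromatic_mask).sum() == h.hue.size

    def test_ranges(self, scene):
        h = ss.rgb_to_hsl(scene.image)
        assert h.hue.min() >= 0 and h.hue.max() < 360
        assert h.saturation.min() >= 0 and h.saturation.max() <= 1
        assert h.lightness.min() >= 0 and h.lightness.max() <= 1

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255)))
    def test_roundtrip_through_hsl_is_lossless(self, rgb):
        """8-bit RGB -> HSL -> RGB -> HSL reproduces hue within 1.5 degrees
        and S, L within 1/255 (it is in fact exact for 8-bit inputs)."""
        px = np.array([[rgb]], np.uint8)
        h1 = ss.rgb_to_hsl(px)
        back = np.round(ss.hsl_to_rgb(h1.hue, h1.saturation, h1.lightness) * 255).astype(np.uint8)
        h2 = ss.rgb_to_hsl(back)
        dh = abs(h2.hue[0, 0] - h1.hue[0, 0])
        assert min(dh, 360 - dh) <= 1.5
        assert abs(h2.saturation[0, 0] - h1.saturation[0, 0]) <= 1 / 255
        assert abs(h2.lightness[0, 0] - h1.lightness[0, 0]) <= 1 / 255
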