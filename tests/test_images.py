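"""Preprocessing chain: I/O, ROI, grey conversion, high-pass, levels, quantization."""

import numpy as np
import pytest
from scipy import ndimage

from mucotex.exceptions import DegenerateDataError, ValidationError
from mucotex.images import (GreyImage, RgbImage, RoiSpec, equalize_levels, extract_roi,
                            high_pass, load_image, preprocess, quantize, save_image,
                            to_grey)


class TestIO:
    @pytest.mark.parametrize("suffix", [".tif", ".png"])
    def test_rgb_roundtrip(self, tmp_path, rng, suffix):
        img = RgbImage(rng.integers(0, 256, size=(40, 50, 3)))
        path = tmp_path / f"img{suffix}"
        save_image(img, path)
        back = load_image(path)
        assert isinstance(back, RgbImage)
        np.testing.assert_array_equal(back.pixels, img.pixels)

    def test_grey_roundtrip(self, tmp_path, rng):
        img = GreyImage(rng.integers(0, 256, size=(30, 30)), bit_depth=8)
        path = tmp_path / "img.png"
        save_image(img, path)
        back = load_image(path)
        assert isinstance(back, GreyImage)
        assert back.n_levels == 256
        np.testing.assert_array_equal(back.pixels, img.pixels)

    def test_truncated_file_raises(self, tmp_path):
        path = tmp_path / "broken.tif"
        path.write_bytes(b"II*\x00\x08")
        with pytest.raises(OSError, match="broken.tif"):
            load_image(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(OSError):
            load_image(tmp_path / "absent.png")


class TestRoi:
    def test_centered_crop(self, rng):
        img = GreyImage(rng.integers(0, 256, size=(600, 600)))
        sub = extract_roi(img, RoiSpec.centered(600, 600))
        assert (sub.height, sub.width) == (300, 300)
        np.testing.assert_array_equal(sub.pixels, img.pixels[150:450, 150:450])

    def test_whole_image_identity(self, rng):
        img = GreyImage(rng.integers(0, 256, size=(20, 30)))
        sub = extract_roi(img, RoiSpec(0, 0, 20, 30))
        np.testing.assert_array_equal(sub.pixels, img.pixels)

    def test_out_of_bounds_rejected(self, rng):
        img = GreyImage(rng.integers(0, 256, size=(20, 30)))
        with pytest.raises(ValidationError):
            extract_roi(img, RoiSpec(0, 25, 10, 10))

    def test_nested_crops_compose(self, rng):
        img = GreyImage(rng.integers(0, 256, size=(100, 100)))
        once = extract_roi(extract_roi(img, RoiSpec(10, 20, 60, 60)), RoiSpec(5, 7, 30, 30))
        combined = extract_roi(img, RoiSpec(15, 27, 30, 30))
        np.testing.assert_array_equal(once.pixels, combined.pixels)


class TestToGrey:
    @pytest.mark.parametrize("rgb,expected", [((255, 255, 255), 255), ((0, 0, 0), 0),
                                              ((100, 100, 100), 100)])
    def test_achromatic_pixels(self, rgb, expected):
        img = RgbImage(np.full((2, 2, 3), rgb, dtype=np.uint8))
        assert to_grey(img).pixels[0, 0] == expected

    def test_rec601_weights(self):
        img = RgbImage(np.array([[[200, 50, 10]]], dtype=np.uint8))
        expected = round(0.299 * 200 + 0.587 * 50 + 0.114 * 10)
        assert to_grey(img).pixels[0, 0] == expected


class TestHighPass:
    @pytest.mark.parametrize("level", [0, 77, 255])
    @pytest.mark.parametrize("radius", [1.0, 10.0])
    def test_constant_maps_to_midgrey(self, level, radius):
        img = GreyImage(np.full((32, 32), level))
        out = high_pass(img, radius=radius)
        assert (out.pixels == 128).all()

    def test_impulse_response(self):
        px = np.zeros((41, 41), dtype=np.uint8)
        px[20, 20] = 255
        out = high_pass(GreyImage(px), radius=3.0)
        assert out.pixels[20, 20] > 200       # strong positive response at the spike
        assert abs(int(out.pixels[0, 0]) - 128) <= 1  # flat far away

    def test_noise_mean_near_midgrey(self, rng):
        img = GreyImage(rng.integers(0, 256, size=(64, 64)))
        out = high_pass(img, radius=10.0)
        assert abs(out.pixels.mean() - 128) < 2

    def test_matches_direct_convolution(self, rng):
        """Residual against an independently blurred image (same boundary rule)."""
        img = GreyImage(rng.integers(0, 256, size=(32, 32)))
        blur = ndimage.gaussian_filter(img.pixels.astype(float), 4.0, mode="reflect")
        expected = np.clip(np.rint(img.pixels - blur + 128), 0, 255)
        np.testing.assert_array_equal(high_pass(img, radius=4.0).pixels, expected)

    def test_bad_radius(self):
        with pytest.raises(ValidationError):
            high_pass(GreyImage(np.zeros((4, 4))), radius=0)


class TestEqualize:
    def test_midrange_levels_stretch_to_full(self, rng):
        px = rng.integers(64, 192, size=(50, 50))
        px.flat[0], px.flat[1] = 64, 191
        out = equalize_levels(GreyImage(px))
        assert out.pixels.min() == 0 and out.pixels.max() == 255

    def test_full_range_unchanged(self, rng):
        px = rng.integers(0, 256, size=(50, 50))
        px.flat[0], px.flat[1] = 0, 255
        out = equalize_levels(GreyImage(px))
        np.testing.assert_array_equal(out.pixels, px)

    def test_two_level_image(self):
        px = np.array([[100, 150], [150, 100]])
        out = equalize_levels(GreyImage(px))
        assert set(out.pixels.ravel()) == {0, 255}

    def test_constant_rejected(self):
        with pytest.raises(DegenerateDataError):
            equalize_levels(GreyImage(np.full((4, 4), 9)))

    def test_rank_mode_attains_extremes(self, rng):
        out = equalize_levels(GreyImage(rng.integers(100, 130, size=(64, 64))), mode="rank")
        assert out.pixels.max() == 255


class TestQuantize:
    @pytest.mark.parametrize("level,expected", [(255, 15), (0, 0), (128, 8)])
    def test_bin_edges(self, level, expected):
        out = quantize(GreyImage(np.full((2, 2), level)), bit_depth=4)
        assert out.pixels[0, 0] == expected and out.n_levels == 16

    def test_monotone_over_all_levels(self):
        levels = np.arange(256).reshape(16, 16)
        for bits in (1, 3, 4, 8):
            q = quantize(GreyImage(levels), bit_depth=bits).pixels.ravel()
            assert (np.diff(q.astype(int)) >= 0).all()
            assert q.min() == 0 and q.max() == 2**bits - 1

    def test_bad_depth(self):
        with pytest.raises(ValidationError):
            quantize(GreyImage(np.zeros((2, 2))), bit_depth=9)


def test_full_chain_yields_16_levels(rng):
    img = RgbImage(rng.integers(0, 256, size=(300, 300, 3)))
    out = preprocess(img)
    assert out.n_levels == 16
    assert out.pixels.min() >= 0 and out.pixels.max() <= 15
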