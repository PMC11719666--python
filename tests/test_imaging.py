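"""Color-space conversions and foreground chromaticity statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from seedvision import SeedImage, color_features, read_image, rgb_to_hsi, rgb_to_lab

# --------------------------------------------------------------------------
# independent reference conversion: sRGB (D65, 2 deg) -> XYZ -> CIELAB,
# coded directly from the standard formulas, separate from the production path

_M_RGB_TO_XYZ = np.array([
    [0.4124564, 0.3575761, 0.1804375],
    [0.2126729, 0.7151522, 0.0721750],
    [0.0193339, 0.1191920, 0.9503041],
])
_WHITE_D65 = np.array([0.95047, 1.0, 1.08883])


def _srgb_decode(c):
    c = np.asarray(c, dtype=np.float64)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _f(t):
    delta = 6.0 / 29.0
    return np.where(t > delta ** 3, np.cbrt(t), t / (3 * delta ** 2) + 4.0 / 29.0)


def lab_reference(rgb255):
    rgb_lin = _srgb_decode(np.asarray(rgb255, dtype=np.float64) / 255.0)
    xyz = _M_RGB_TO_XYZ @ rgb_lin
    fx, fy, fz = _f(xyz / _WHITE_D65)
    return np.array([116 * fy - 16, 500 * (fx - fy), 200 * (fy - fz)])


def rgb_reference_from_lab(lab):
    L, a, b = lab
    fy = (L + 16) / 116
    fx = fy + a / 500
    fz = fy - b / 200
    delta = 6.0 / 29.0

    def finv(t):
        return np.where(t > delta, t ** 3, 3 * delta ** 2 * (t - 4.0 / 29.0))

    xyz = finv(np.array([fx, fy, fz])) * _WHITE_D65
    rgb_lin = np.linalg.solve(_M_RGB_TO_XYZ, xyz)
    rgb = np.where(rgb_lin <= 0.0031308, 12.92 * rgb_lin,
                   1.055 * np.clip(rgb_lin, 0, None) ** (1 / 2.4) - 0.055)
    return np.clip(rgb, 0, 1) * 255.0


def _single_pixel(rgb):
    return np.full((2, 2, 3), rgb, dtype=np.uint8)


# --------------------------------------------------------------------------
# read_image

class TestReadImage:
    def test_white_png_identity(self, tmp_path):
        path = tmp_path / "white.png"
        Image.fromarray(np.full((2, 2, 3), 255, dtype=np.uint8)).save(path)
        img = read_image(path)
        assert img.pixels.shape == (2, 2, 3)
        assert (img.pixels == 255).all()

    def test_bgr_on_disk_decodes_to_rgb(self, tmp_path):
        # BMP stores channels in BGR order on disk; the loader must still
        # return RGB
        path = tmp_path / "red.bmp"
        Image.fromarray(_single_pixel((255, 0, 0))).save(path)
        img = read_image(path)
        assert tuple(img.pixels[0, 0]) == (255, 0, 0)

    def test_sixteen_bit_rescaled(self, tmp_path):
        path = tmp_path / "deep.tif"
        arr = np.full((4, 4), 65535, dtype=np.uint16)
        Image.fromarray(arr).save(path)
        with pytest.warns(UserWarning):
            img = read_image(path)
        assert img.pixels.max() == 255

    def test_grayscale_converted_with_warning(self, tmp_path):
        path = tmp_path / "gray.png"
        Image.fromarray(np.full((4, 4), 128, dtype=np.uint8)).save(path)
        with pytest.warns(UserWarning, match="converted"):
            img = read_image(path)
        assert img.pixels.shape == (4, 4, 3)

    def test_truncated_file_raises(self, tmp_path):
        path = tmp_path / "broken.png"
        good = tmp_path / "good.png"
        Image.fromarray(np.zeros((8, 8, 3), dtype=np.uint8)).save(good)
        path.write_bytes(good.read_bytes()[:20])
        with pytest.raises(OSError, match="broken.png"):
            read_image(path)

    def test_missing_file_raises_with_path(self, tmp_path):
        with pytest.raises(OSError, match="nowhere.png"):
            read_image(tmp_path / "nowhere.png")


# --------------------------------------------------------------------------
# CIELAB

class TestRgbToLab:
    @pytest.mark.parametrize("rgb,expected", [
        ((255, 255, 255), (100.0, 0.0, 0.0)),   # white point
        ((119, 119, 119), (None, 0.0, 0.0)),    # neutral axis: a* = b* = 0
    ])
    def test_reference_points(self, rgb, expected):
        lab = rgb_to_lab(_single_pixel(rgb))[0, 0]
        for got, want in zip(lab, expected):
            if want is not None:
                assert got == pytest.approx(want, abs=1e-2)

    @pytest.mark.parametrize("rgb", [(255, 0, 0), (0, 255, 0), (0, 0, 255),
                                     (200, 150, 100)])
    def test_against_independent_reference(self, rgb):
        lab = rgb_to_lab(_single_pixel(rgb))[0, 0]
        ref = lab_reference(rgb)
        assert np.allclose(lab, ref, atol=1e-2)

    def test_round_trip_recovers_rgb(self, rng):
        pixels = rng.integers(0, 256, size=(10, 10, 3)).astype(np.uint8)
        lab = rgb_to_lab(pixels)
        back = np.array([[rgb_reference_from_lab(lab[i, j])
                          for j in range(10)] for i in range(10)])
        assert np.abs(back - pixels.astype(float)).max() <= 1.0


# --------------------------------------------------------------------------
# HSI

class TestRgbToHsi:
    def test_gray_pixel_conventions(self):
        h, s, i = rgb_to_hsi(_single_pixel((128, 128, 128)))[0, 0]
        assert (h, s, i) == (0.0, 0.0, 128.0)

    def test_black_pixel_conventions(self):
        h, s, i = rgb_to_hsi(_single_pixel((0, 0, 0)))[0, 0]
        assert (h, s, i) == (0.0, 0.0, 0.0)

    def test_pure_red(self):
        h, s, i = rgb_to_hsi(_single_pixel((255, 0, 0)))[0, 0]
        assert h == pytest.approx(0.0, abs=1e-9)
        assert s == pytest.approx(1.0)
        assert i == pytest.approx(85.0)

    def test_pure_green_hue(self):
        # oracle: direct evaluation of the arccos hue formula at (0,255,0)
        # gives arccos(-1/2) = 120 degrees
        h = rgb_to_hsi(_single_pixel((0, 255, 0)))[0, 0, 0]
        assert h == pytest.approx(120.0, abs=1e-6)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.tuples(st.integers(0, 255), st.integers(0, 255),
                     st.integers(0, 255)))
    def test_any_pixel_within_channel_ranges(self, rgb):
        h, s, i = rgb_to_hsi(_single_pixel(rgb))[0, 0]
        assert 0 <= h < 360
        assert 0 <= s <= 1
        assert i == pytest.approx(sum(rgb) / 3)
        if len(set(rgb)) == 1:   # achromatic pixels pin hue and saturation
            assert h == 0.0 and s == 0.0

    def test_ranges_on_random_pixels(self, rng):
        px = rng.integers(0, 256, size=(32, 32, 3)).astype(np.uint8)
        hsi = rgb_to_hsi(px)
        assert hsi[..., 0].min() >= 0 and hsi[..., 0].max() < 360
        assert hsi[..., 1].min() >= 0 and hsi[..., 1].max() <= 1
        assert np.allclose(hsi[..., 2], px.astype(float).mean(axis=-1))


# --------------------------------------------------------------------------
# foreground statistics

class TestColorFeatures:
    def test_uniform_region(self):
        img = np.full((8, 8, 3), (200, 150, 100), dtype=np.uint8)
        mask = np.ones((8, 8), dtype=bool)
        f = color_features(img, mask)
        assert f.mean_R == 200 and f.mean_G == 150 and f.mean_B == 100
        for name in ("R", "G", "B", "Lstar", "astar", "bstar", "H", "S", "I"):
            assert getattr(f, f"sd_{name}") == pytest.approx(0.0, abs=1e-5)

    def test_two_point_population_statistics(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0] = 0
        img[1] = 255
        f = color_features(img, np.ones((2, 2), dtype=bool))
        assert f.mean_I == pytest.approx(127.5)
        assert f.sd_R == pytest.approx(127.5)  # population, not sample, SD

    def test_hue_mean_is_circular(self):
        # two hues straddling the 0/360 wrap must average near 0, not 180
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[0] = (200, 50, 52)   # hue just below 360
        img[1] = (200, 52, 50)   # hue just above 0
        f = color_features(img, np.ones((2, 2), dtype=bool))
        assert min(f.mean_H, 360 - f.mean_H) < 5.0

    def test_permutation_invariance(self, rng):
        px = rng.integers(0, 256, size=(6, 6, 3)).astype(np.uint8)
        mask = np.ones((6, 6), dtype=bool)
        perm = rng.permutation(36)
        shuffled = px.reshape(36, 3)[perm].reshape(6, 6, 3)
        f1 = color_features(px, mask).to_dict()
        f2 = color_features(shuffled, mask).to_dict()
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-9)

    def test_mask_equals_crop(self, rng):
        px = rng.integers(0, 256, size=(12, 12, 3)).astype(np.uint8)
        mask = np.zeros((12, 12), dtype=bool)
        mask[3:9, 4:10] = True
        f_masked = color_features(px, mask).to_dict()
        crop = px[3:9, 4:10]
        f_crop = color_features(crop, np.ones((6, 6), dtype=bool)).to_dict()
        for k in f_masked:
            assert f_masked[k] == pytest.approx(f_crop[k], abs=1e-9)

    def test_empty_mask_rejected(self):
        img = np.zeros((4, 4, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="mask"):
            color_features(img, np.zeros((4, 4), dtype=bool))

    def test_seed_image_mask_used_by_default(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1:3, 1:3] = True
        img = SeedImage(pixels=np.full((4, 4, 3), 10, dtype=np.uint8), mask=mask)
        assert color_features(img).mean_R == 10
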