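import numpy as np
import pytest

from lampseg.image_model import RGBImage
from lampseg.optical_features import (
    brightest_point,
    channel_variation,
    compute_feature_maps,
    global_intensity_contrast,
    intensity_position,
    normalize_map,
    red_channel_contrast,
)

from conftest import naive_contrast_quantized


class TestGlobalContrast:
    def test_constant_image_all_zero(self):
        assert np.array_equal(global_intensity_contrast(np.full((4, 4), 0.3)), np.zeros((4, 4)))

    def test_three_pixel_example(self):
        # intensities (0, 5, 10)/255: pairwise |diff| sums are (15, 10, 15)/255
        inten = np.array([[0, 5, 10]]) / 255.0
        expected = np.array([[15, 10, 15]]) / 255.0
        assert global_intensity_contrast(inten) == pytest.approx(expected, abs=1e-15)

    def test_histogram_equals_naive_double_sum(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            vals = rng.integers(0, 256, size=(16, 16)) / 255.0
            fast = global_intensity_contrast(vals)
            slow = naive_contrast_quantized(vals)
            assert np.array_equal(fast, slow)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 256, size=(6, 7)) / 255.0
        perm = rng.permutation(vals.size)
        base = global_intensity_contrast(vals).ravel()
        shuffled = global_intensity_contrast(vals.ravel()[perm].reshape(vals.shape)).ravel()
        assert np.allclose(shuffled, base[perm])


class TestRedChannelContrast:
    def test_matches_intensity_contrast_on_gray_images(self):
        rng = np.random.default_rng(1)
        gray = rng.integers(0, 256, size=(8, 8)) / 255.0
        img = RGBImage(np.repeat(gray[..., None], 3, axis=2))
        assert np.array_equal(red_channel_contrast(img), global_intensity_contrast(gray))

    def test_three_pixel_red_example(self):
        px = np.zeros((1, 3, 3))
        px[0, :, 0] = np.array([0, 5, 10]) / 255.0
        # needs H, W >= 2: tile the row; contrast doubles with the pixel count
        img = RGBImage(np.tile(px, (2, 1, 1)))
        expected = 2 * np.array([15, 10, 15]) / 255.0
        assert red_channel_contrast(img)[0] == pytest.approx(expected, abs=1e-15)


class TestChannelVariation:
    def test_achromatic_pixels_zero_to_rounding(self):
        img = RGBImage(np.repeat(np.random.default_rng(0).random((3, 3, 1)), 3, axis=2))
        assert np.allclose(channel_variation(img), 0.0, atol=1e-30)

    @pytest.mark.parametrize(
        "pixel, expected",
        [((1, 0, 0), 2 / 3), ((1, 1, 0), 2 / 3), ((0.5, 0.5, 0.5), 0.0)],
    )
    def test_sum_of_squared_deviations(self, pixel, expected):
        img = RGBImage(np.tile(np.array(pixel, dtype=float), (2, 2, 1)))
        assert channel_variation(img) == pytest.approx(np.full((2, 2), expected))


class TestBrightestPoint:
    def test_unique_maximum(self):
        m = np.zeros((5, 6))
        m[2, 3] = 0.9
        assert brightest_point(m) == (2, 3)

    def test_ties_resolve_row_major_first(self):
        assert brightest_point(np.ones((4, 4))) == (0, 0)
        m = np.zeros((4, 6))
        m[1, 5] = m[3, 0] = 1.0
        assert brightest_point(m) == (1, 5)


class TestIntensityPosition:
    def test_value_one_at_source_and_zero_after_normalization(self):
        raw = intensity_position((5, 5), (2, 2))
        assert raw[2, 2] == pytest.approx(1.0)
        assert normalize_map(raw)[2, 2] == 0.0

    def test_two_pixel_row_example(self):
        # 1x2 image, diagonal sqrt(5): raw map is (1, exp(1/sqrt 5))
        raw = intensity_position((1, 2), (0, 0))
        assert raw == pytest.approx(np.array([[1.0, np.exp(1 / np.sqrt(5))]]))

    def test_strictly_monotone_in_distance(self):
        raw = intensity_position((9, 11), (4, 5))
        rows, cols = np.indices((9, 11))
        dist = np.hypot(rows - 4, cols - 5)
        order = np.argsort(dist.ravel())
        d_sorted = dist.ravel()[order]
        v_sorted = raw.ravel()[order]
        increasing = np.diff(d_sorted) > 0
        assert np.all(np.diff(v_sorted)[increasing] > 0)
        assert np.unravel_index(np.argmin(raw), raw.shape) == (4, 5)

    def test_out_of_bounds_source_rejected(self):
        with pytest.raises(ValueError):
            intensity_position((4, 4), (4, 0))


class TestNormalizeMap:
    def test_affine_stretch(self):
        assert normalize_map(np.array([0.0, 5.0, 10.0])) == pytest.approx([0, 0.5, 1])

    def test_constant_maps_to_zeros(self):
        assert np.array_equal(normalize_map(np.full((3, 3), 2.5)), np.zeros((3, 3)))

    def test_idempotent(self):
        x = np.random.default_rng(5).random((4, 4))
        once = normalize_map(x)
        assert np.allclose(normalize_map(once), once)


def test_feature_bundle_shapes_and_ranges(default_lit_scene):
    maps = compute_feature_maps(default_lit_scene.image)
    for m in (maps.ci, maps.vc, maps.dd, maps.cr):
        assert m.shape == default_lit_scene.image.shape
        assert m.min() == 0.0 and m.max() == 1.0
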