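import itertools

import numpy as np
import pytest

from lampseg.image_model import RectWindow, RGBImage
from lampseg.kernel_graphcut import (
    KGCParams,
    kernel_distance,
    optimal_labeling,
    segment,
    smoothness_penalty,
    total_energy,
    update_region_params,
)


def naive_energy(pixels, labels, models, params):
    """Independent double-sum re-implementation of the objective."""
    h, w = labels.shape
    e = 0.0
    for r in range(h):
        for c in range(w):
            u = models[labels[r, c]]
            sq = float(((pixels[r, c] - u) ** 2).sum())
            e += 2.0 * (1.0 - np.exp(-sq / params.sigma**2))
    for r in range(h):
        for c in range(w):
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if rr < h and cc < w:
                    d = float(labels[r, c]) - float(labels[rr, cc])
                    e += params.alpha * min(d * d, params.r_max)
    return e


def exhaustive_best_energy(pixels, models, params):
    h, w = pixels.shape[:2]
    best = np.inf
    for bits in itertools.product((0, 1), repeat=h * w):
        lab = np.array(bits, dtype=np.int64).reshape(h, w)
        best = min(best, total_energy(pixels, lab, models, params))
    return best


class TestKernelDistance:
    def test_zero_at_equal_arguments(self):
        assert kernel_distance(np.array([0.3, 0.3, 0.3]), np.array([0.3, 0.3, 0.3]), 0.1) == 0.0

    def test_bounded_by_two_for_distant_values(self):
        d = kernel_distance(np.array([0.0]), np.array([100.0]), 0.1)
        assert d == pytest.approx(2.0)

    def test_one_sigma_separation(self):
        d = kernel_distance(np.array([0.5]), np.array([0.5 + 0.2]), 0.2)
        assert d == pytest.approx(2 * (1 - np.exp(-1)), rel=1e-12)  # ~1.2642


class TestSmoothnessPenalty:
    @pytest.mark.parametrize("u, v, r_max, expected", [
        (3, 3, 5.0, 0.0),
        (0, 1, 1.0, 1.0),   # Potts-equivalent on binary labels
        (0, 3, 4.0, 4.0),   # truncation
        (0, 2, 9.0, 4.0),
    ])
    def test_truncated_square(self, u, v, r_max, expected):
        assert smoothness_penalty(u, v, r_max) == expected


class TestTotalEnergy:
    def test_matches_naive_double_sum_on_random_instances(self):
        rng = np.random.default_rng(21)
        params = KGCParams(alpha=0.7, sigma=0.3)
        for _ in range(10):
            pixels = rng.random((4, 4, 3))
            labels = rng.integers(0, 2, size=(4, 4))
            models = rng.random((2, 3))
            assert total_energy(pixels, labels, models, params) == pytest.approx(
                naive_energy(pixels, labels, models, params)
            )

    def test_zero_for_perfect_single_region(self):
        pixels = np.full((3, 3, 3), 0.4)
        labels = np.zeros((3, 3), dtype=np.int64)
        models = np.array([[0.4, 0.4, 0.4]])
        p = KGCParams(alpha=5.0)
        assert total_energy(pixels, labels, models, p) == 0.0

    def test_block_partition_boundary_bookkeeping(self):
        # two half-planes, matching labels: data 0, boundary = 3 pairs * alpha
        pixels = np.zeros((3, 2, 3))
        pixels[:, 1] = 1.0
        labels = np.tile(np.array([[0, 1]]), (3, 1))
        models = np.array([[0.0] * 3, [1.0] * 3])
        p = KGCParams(alpha=0.5, r_max=1.0)
        assert total_energy(pixels, labels, models, p) == pytest.approx(3 * 0.5)


class TestUpdateRegionParams:
    def test_constant_region_fixed_point(self):
        pixels = np.full((3, 3, 3), 0.7)
        labels = np.zeros((3, 3), dtype=np.int64)
        models = update_region_params(pixels, labels, sigma=0.1)
        assert models[0] == pytest.approx([0.7, 0.7, 0.7])

    def test_large_sigma_limit_is_region_mean(self):
        rng = np.random.default_rng(22)
        pixels = rng.random((4, 4, 3))
        labels = np.zeros((4, 4), dtype=np.int64)
        models = update_region_params(pixels, labels, sigma=1e6)
        assert models[0] == pytest.approx(pixels.reshape(-1, 3).mean(axis=0), abs=1e-6)

    def test_small_sigma_seeks_the_mode_and_beats_grid_search(self):
        vals = np.concatenate([np.zeros(90), np.ones(10)])
        pixels = np.repeat(vals, 3).reshape(10, 10, 3)
        labels = np.zeros((10, 10), dtype=np.int64)
        sigma = 0.1
        models = update_region_params(pixels, labels, sigma=sigma)
        assert abs(models[0][0]) < 1e-3  # the 90-pixel mode, not the mean
        # energy no worse than a fine grid search over scalar u
        pts = pixels.reshape(-1, 3)
        def energy(u):
            return (2 * (1 - np.exp(-((pts - u) ** 2).sum(1) / sigma**2))).sum()
        grid_best = min(energy(u) for u in np.arange(0, 1.0001, 1e-3))
        assert energy(models[0]) <= grid_best + 1e-9

    def test_empty_label_keeps_previous_model(self):
        pixels = np.full((2, 2, 3), 0.5)
        labels = np.zeros((2, 2), dtype=np.int64)
        prev = np.array([[0.1] * 3, [0.9] * 3])
        models = update_region_params(pixels, labels, sigma=0.2, prev_models=prev)
        assert models[1] == pytest.approx([0.9] * 3)


class TestOptimalLabeling:
    def test_alpha_zero_is_pointwise_argmin(self):
        rng = np.random.default_rng(23)
        pixels = rng.random((5, 5, 3))
        models = rng.random((2, 3))
        params = KGCParams(alpha=1e-9, sigma=0.2)
        labels = optimal_labeling(pixels, models, params)
        d0 = kernel_distance(pixels, models[0], 0.2)
        d1 = kernel_distance(pixels, models[1], 0.2)
        assert np.array_equal(labels, (d1 < d0).astype(labels.dtype))

    def test_clean_two_tone_image_recovered_exactly(self):
        pixels = np.zeros((6, 6, 3))
        pixels[:, 3:] = 0.8
        models = np.array([[0.0] * 3, [0.8] * 3])
        labels = optimal_labeling(pixels, models, KGCParams(alpha=0.5, sigma=0.15))
        expected = np.tile(np.arange(6) >= 3, (6, 1)).astype(labels.dtype)
        assert np.array_equal(labels, expected)

    def test_min_cut_energy_matches_exhaustive_search(self):
        rng = np.random.default_rng(24)
        params = KGCParams(alpha=0.4, sigma=0.25)
        for _ in range(20):
            pixels = rng.random((3, 3, 3))
            models = rng.random((2, 3))
            labels = optimal_labeling(pixels, models, params)
            e = total_energy(pixels, labels, models, params)
            assert e == pytest.approx(exhaustive_best_energy(pixels, models, params), rel=1e-9)

    def test_huge_alpha_forces_constant_labeling(self):
        rng = np.random.default_rng(25)
        pixels = rng.random((6, 6, 3))
        models = np.array([[0.2] * 3, [0.8] * 3])
        labels = optimal_labeling(pixels, models, KGCParams(alpha=1e4, sigma=0.2))
        assert len(np.unique(labels)) == 1

    def test_three_label_expansion_never_worse_than_pointwise(self):
        rng = np.random.default_rng(26)
        pixels = rng.random((6, 6, 3))
        models = rng.random((3, 3))
        params = KGCParams(alpha=0.3, sigma=0.3, n_labels=3)
        labels = optimal_labeling(pixels, models, params)
        assert labels.max() <= 2
        pointwise = np.argmin(
            np.stack([kernel_distance(pixels, m, 0.3) for m in models]), axis=0
        )
        e_exp = total_energy(pixels, labels, models, params)
        e_pw = total_energy(pixels, pointwise, models, params)
        assert e_exp <= e_pw + 1e-9


class TestSegment:
    def test_bright_disk_on_dark_background_exact(self):
        rows, cols = np.indices((24, 24))
        disk = np.hypot(rows - 12, cols - 12) <= 6
        px = np.where(disk[..., None], 0.85, 0.15) * np.ones(3)
        img = RGBImage(px)
        res = segment(img, RectWindow(0, 0, 24, 24), KGCParams())
        assert np.array_equal(res.mask.values.astype(bool), disk)
        trace = res.energy_trace
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_mask_embedded_in_full_frame_with_zero_outside(self):
        px = np.full((20, 20, 3), 0.2)
        px[8:12, 8:12] = 0.9
        img = RGBImage(px)
        win = RectWindow(5, 5, 15, 15)
        res = segment(img, win, KGCParams())
        assert res.mask.values.shape == (20, 20)
        outside = res.mask.values.copy()
        outside[5:15, 5:15] = 0
        assert outside.sum() == 0
        assert np.array_equal(np.argwhere(res.mask.values), np.argwhere(px[..., 0] == 0.9))

    def test_object_label_follows_strength_map(self):
        px = np.full((10, 10, 3), 0.2)
        px[:, 5:] = 0.8
        img = RGBImage(px)
        win = RectWindow(0, 0, 10, 10)
        strength_left = np.zeros((10, 10))
        strength_left[:, :5] = 1.0
        res = segment(img, win, KGCParams(), strength=strength_left)
        assert res.mask.values[:, :5].all() and not res.mask.values[:, 5:].any()

    def test_window_must_fit_image(self):
        img = RGBImage(np.full((8, 8, 3), 0.5))
        with pytest.raises(ValueError):
            segment(img, RectWindow(0, 0, 9, 8), KGCParams())

    def test_energy_trace_monotone_on_synthetic_scenes(self, suite_seed0):
        from lampseg.optical_features import compute_feature_maps
        from lampseg.light_recognition import recognize_light
        from lampseg.candidate_region import identify_candidate

        for bundle in [b for b in suite_seed0 if b.spec.lit][:5]:
            dec = recognize_light(compute_feature_maps(bundle.image))
            cand = identify_candidate(dec.w)
            res = segment(bundle.image, cand.window, KGCParams(), strength=dec.w)
            trace = res.energy_trace
            assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))
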