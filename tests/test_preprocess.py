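"""Filters against brute-force neighborhood oracles; histogram equalization
against hand-computed mappings."""

import numpy as np
import pytest

import lungct as lc
from lungct.preprocess import level_probabilities


def brute_average(img, k):
    pad = k // 2
    p = np.pad(np.asarray(img, float), pad)
    out = np.empty_like(np.asarray(img, float))
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = p[i:i + k, j:j + k].mean()
    return out


def brute_median3(img):
    p = np.pad(np.asarray(img, float), 1)
    out = np.empty_like(np.asarray(img, float))
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            nb = np.sort(p[i:i + 3, j:j + 3].ravel())
            out[i, j] = nb[4]  # center of the ascending 9-element sort
    return out


class TestAverageFilter:
    def test_constant_image_interior_unchanged(self):
        img = np.full((8, 8), 5.0)
        out = lc.average_filter(img, 3)
        assert np.allclose(out[1:-1, 1:-1], 5.0)

    def test_center_impulse_hand_value(self):
        img = np.zeros((3, 3))
        img[1, 1] = 9.0
        assert lc.average_filter(img, 3)[1, 1] == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_brute_force_oracle(self, seed):
        img = np.random.default_rng(seed).integers(0, 256, (16, 16))
        assert np.allclose(lc.average_filter(img, 3), brute_average(img, 3),
                           atol=1e-12)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            lc.average_filter(np.zeros((5, 5)), 4)


class TestMedianFilter:
    def test_constant_interior_unchanged(self):
        img = np.full((6, 6), 3.0)
        assert np.allclose(lc.median_filter3(img)[1:-1, 1:-1], 3.0)

    def test_single_salt_pixel_restored(self):
        img = np.full((5, 5), 10.0)
        img[2, 2] = 255.0
        assert lc.median_filter3(img)[2, 2] == 10.0

    def test_corner_of_ones_is_zero_from_padding(self):
        # corner neighborhood holds five padded zeros and four ones
        img = np.ones((4, 4))
        assert lc.median_filter3(img)[0, 0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_exhaustive_5x5_against_oracle(self, seed):
        img = np.random.default_rng(seed).integers(0, 256, (5, 5))
        assert np.array_equal(lc.median_filter3(img), brute_median3(img))
        assert np.allclose(lc.average_filter(img, 3), brute_average(img, 3))


class TestAdaptiveMedianFilter:
    def test_identity_on_smooth_impulse_free_image(self):
        # a smooth ramp: every interior pixel lies strictly between its
        # window min and max, so stage B passes it through unchanged
        yy, xx = np.mgrid[0:20, 0:20]
        img = 0.2 + 0.5 * (yy + 2 * xx) / 60.0
        out = lc.adaptive_median_filter(img, s_max=7)
        interior = np.s_[3:-3, 3:-3]  # borders see padded zeros
        assert np.array_equal(out[interior], img[interior])

    def test_non_extreme_pixels_pass_through_on_noise(self):
        rng = np.random.default_rng(0)
        img = 0.3 + 0.4 * rng.random((20, 20))  # no 0/1 impulses
        out = lc.adaptive_median_filter(img, s_max=7)
        interior = np.s_[3:-3, 3:-3]
        from scipy import ndimage

        zmin = ndimage.minimum_filter(img, size=3, mode="constant")
        zmax = ndimage.maximum_filter(img, size=3, mode="constant")
        keep = (zmin < img) & (img < zmax)
        assert np.array_equal(out[interior][keep[interior]],
                              img[interior][keep[interior]])

    def test_reduces_mae_at_ten_percent_salt_pepper(self, small_phantom_cfg):
        clean = lc.generate_phantom(
            small_phantom_cfg.replace(gaussian_sigma=0.0, sp_density=0.0),
            seed=5).image
        noisy = lc.add_noise(clean, sigma=0.0, sp_density=0.10, seed=6)
        filtered = lc.adaptive_median_filter(noisy, s_max=7)
        assert (np.abs(filtered - clean).mean()
                < np.abs(noisy - clean).mean())

    def test_beats_plain_median_at_twenty_percent_impulses(
            self, small_phantom_cfg):
        clean = lc.generate_phantom(
            small_phantom_cfg.replace(gaussian_sigma=0.0, sp_density=0.0),
            seed=7).image
        noisy = lc.add_noise(clean, sigma=0.0, sp_density=0.20, seed=8)

        def residual_impulses(img):
            # interior only: the zero padding itself creates 0.0 outputs
            inner = img[4:-4, 4:-4]
            return np.sum((inner == 0.0) | (inner == 1.0))

        adaptive = lc.adaptive_median_filter(noisy, s_max=7)
        plain = lc.median_filter3(noisy)
        assert residual_impulses(adaptive) < residual_impulses(plain)

    def test_oversized_window_rejected(self):
        with pytest.raises(ValueError):
            lc.adaptive_median_filter(np.zeros((5, 5)), s_max=7)


class TestHistogramEqualize:
    def test_level_probabilities_sum_to_one(self):
        img = np.random.default_rng(1).integers(0, 256, (32, 32))
        assert level_probabilities(img) .sum() == pytest.approx(1.0)

    def test_two_level_hand_mapping(self):
        # 50% zeros, 50% full scale: CDF = (.5, 1) -> levels {127, 255}
        img = np.zeros((10, 10), dtype=np.int64)
        img[:, 5:] = 255
        out = lc.histogram_equalize(img)
        assert set(np.unique(out)) == {127, 255}
        assert np.all(out[:, :5] == 127)
        assert np.all(out[:, 5:] == 255)

    def test_constant_image_stays_constant(self):
        img = np.full((8, 8), 42, dtype=np.int64)
        out = lc.histogram_equalize(img)
        assert len(np.unique(out)) == 1

    def test_output_cdf_near_uniform_within_largest_bin(self):
        # classical bound: max CDF deviation <= largest input bin mass,
        # plus one level of rounding slack from the integer remap
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, (64, 64))
        out = lc.histogram_equalize(img)
        p_in = level_probabilities(img)
        p_out = level_probabilities(out)
        dev = np.max(np.abs(np.cumsum(p_out)
                            - np.arange(1, 257) / 256))
        assert dev <= p_in.max() + 1 / 255 + 1e-12

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            lc.histogram_equalize(np.zeros((0, 0)))
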