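import math

import numpy as np
import pytest

from vhfilter.metrics import (
    PSNR_CAP_DB,
    EMEConfig,
    alpha_rooting,
    apply_reference_filter,
    eme,
    entropy,
    error_metrics,
    full_report,
    ssim,
)

C1 = (0.01 * 255) ** 2


class TestErrorMetrics:
    def test_identical_images(self, small_gray):
        em = error_metrics(small_gray, small_gray)
        assert em.mse == 0 and em.mae == 0 and em.nae == 0
        assert em.ncc == pytest.approx(1.0)
        assert em.psnr == PSNR_CAP_DB

    def test_hand_computed_2x2(self):
        o = np.array([[10, 20], [30, 40]], dtype=np.uint8)
        r = np.array([[12, 18], [33, 44]], dtype=np.uint8)
        em = error_metrics(o, r)
        assert em.mse == pytest.approx(8.25)
        assert em.psnr == pytest.approx(10 * math.log10(255**2 / 8.25), rel=1e-9)
        assert em.psnr == pytest.approx(38.9668, abs=1e-3)
        assert em.mae == pytest.approx((2 + 2 + 3 + 4) / 4)
        assert em.nae == pytest.approx(11 / 100)
        assert em.ncc == pytest.approx(
            (10 * 12 + 20 * 18 + 30 * 33 + 40 * 44) / (10**2 + 20**2 + 30**2 + 40**2)
        )

    def test_extreme_case(self):
        o = np.full((4, 4), 255, dtype=np.uint8)
        r = np.zeros((4, 4), dtype=np.uint8)
        em = error_metrics(o, r)
        assert em.mse == 255**2
        assert em.nae == pytest.approx(1.0)
        assert em.ncc == 0.0

    def test_all_zero_reference_signals_nan(self):
        o = np.zeros((4, 4), dtype=np.uint8)
        r = np.ones((4, 4), dtype=np.uint8)
        with pytest.warns(UserWarning):
            em = error_metrics(o, r)
        assert math.isnan(em.nae) and math.isnan(em.ncc)
        assert em.mse == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            error_metrics(np.zeros((4, 4)), np.zeros((4, 5)))

    def test_permutation_invariance(self, rng, small_gray):
        o = small_gray
        r = np.clip(o.astype(int) + rng.integers(-20, 20, o.shape), 0, 255).astype(np.uint8)
        perm = rng.permutation(o.size)
        em1 = error_metrics(o, r)
        em2 = error_metrics(
            o.ravel()[perm].reshape(o.shape), r.ravel()[perm].reshape(o.shape)
        )
        for a, b in zip(em1, em2):
            assert a == pytest.approx(b)


class TestSSIM:
    def test_self_similarity(self, small_gray):
        assert ssim(small_gray, small_gray) == pytest.approx(1.0)

    def test_symmetry(self, rng, small_gray):
        other = np.clip(
            small_gray.astype(int) + rng.integers(-30, 30, small_gray.shape), 0, 255
        ).astype(np.uint8)
        assert ssim(small_gray, other) == pytest.approx(ssim(other, small_gray))

    def test_constant_images_closed_form(self):
        v, d = 100, 20
        a = np.full((16, 16), v, dtype=np.uint8)
        b = np.full((16, 16), v + d, dtype=np.uint8)
        expected = (2 * v * (v + d) + C1) / (v**2 + (v + d) ** 2 + C1)
        assert ssim(a, b) == pytest.approx(expected, rel=1e-9)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((5, 5), dtype=np.uint8), np.zeros((5, 5), dtype=np.uint8))


class TestEntropy:
    def test_constant(self):
        assert entropy(np.full((8, 8), 42, dtype=np.uint8)) == 0.0

    def test_two_equiprobable_levels(self):
        img = np.zeros((8, 8), dtype=np.uint8)
        img[:, 4:] = 255
        assert entropy(img) == pytest.approx(1.0)

    def test_uniform_256(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        assert entropy(img) == pytest.approx(8.0)

    def test_upper_bound(self, rng):
        img = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        assert entropy(img) <= 8.0


class TestEME:
    def test_constant_is_zero(self):
        assert eme(np.full((32, 32), 99, dtype=np.uint8)) == pytest.approx(0.0, abs=1e-9)

    def test_single_block_closed_form(self):
        img = np.full((8, 8), 100, dtype=np.uint8)
        img[0, 0] = 200
        cfg = EMEConfig(k1=1, k2=1, epsilon=1e-12)
        assert eme(img, cfg) == pytest.approx(20 * math.log10(2), rel=1e-6)

    def test_matches_block_loop(self, rng):
        img = rng.integers(1, 256, (32, 32), dtype=np.uint8)
        cfg = EMEConfig(k1=4, k2=4, epsilon=1e-4)
        total = 0.0
        for bi in range(4):
            for bj in range(4):
                block = img[bi * 8 : (bi + 1) * 8, bj * 8 : (bj + 1) * 8].astype(float)
                total += 20 * math.log10((block.max() + 1e-4) / (block.min() + 1e-4))
        assert eme(img, cfg) == pytest.approx(total / 16, rel=1e-9)

    def test_nonnegative(self, rng):
        img = rng.integers(0, 256, (30, 45), dtype=np.uint8)
        assert eme(img) >= 0.0

    def test_partial_blocks_included(self):
        # 10x10 with 8-pixel blocks -> 2x2 block grid covering everything
        img = np.zeros((10, 10), dtype=np.uint8)
        img[9, 9] = 255
        assert eme(img) > 0.0


class TestAlphaRooting:
    def test_identity_at_alpha_one(self, small_gray):
        out = alpha_rooting(small_gray, 1.0)
        assert np.max(np.abs(out.astype(int) - small_gray.astype(int))) <= 1

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 0.8, 1.1, 1.5])
    def test_output_contract(self, small_gray, alpha):
        out = alpha_rooting(small_gray, alpha)
        assert out.dtype == np.uint8
        assert out.shape == small_gray.shape

    def test_nonpositive_alpha_rejected(self, small_gray):
        with pytest.raises(ValueError):
            alpha_rooting(small_gray, 0.0)

    def test_eme_trend_over_alpha(self, smear_gray):
        # empirical counterpart of the reported monotone EME-vs-alpha column
        alphas = [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1]
        emes = [eme(alpha_rooting(smear_gray, a)) for a in alphas]
        nondecreasing = sum(b >= a for a, b in zip(emes, emes[1:]))
        assert nondecreasing >= 0.8 * (len(alphas) - 1)


class TestReferenceFilters:
    def test_mean_constant_fixed_point(self):
        img = np.full((9, 9), 88, dtype=np.uint8)
        assert np.array_equal(apply_reference_filter(img, "mean3x3"), img)

    def test_mean_matches_nine_term_oracle(self, rng):
        img = rng.integers(0, 256, (8, 8), dtype=np.uint8)
        out = apply_reference_filter(img, "mean3x3")
        for i in range(1, 7):
            for j in range(1, 7):
                s = int(img[i - 1 : i + 2, j - 1 : j + 2].astype(int).sum())
                assert out[i, j] == math.floor(s / 9 + 0.5)

    def test_he_flattens_histogram(self, smear_gray):
        # a monotone remap cannot raise fine-grained entropy, but the
        # coarse-binned histogram must become more uniform
        def coarse_entropy(img, bins=32):
            counts, _ = np.histogram(img, bins=bins, range=(0, 256))
            p = counts[counts > 0] / counts.sum()
            return float(-(p * np.log2(p)).sum())

        out = apply_reference_filter(smear_gray, "histogram_equalization")
        assert coarse_entropy(out) >= coarse_entropy(smear_gray)

    def test_wiener_runs_and_preserves_shape(self, small_gray):
        out = apply_reference_filter(small_gray, "wiener3x3")
        assert out.shape == small_gray.shape
        assert out.dtype == np.uint8

    def test_wiener_constant_image_finite(self):
        img = np.full((9, 9), 77, dtype=np.uint8)
        out = apply_reference_filter(img, "wiener3x3")
        assert np.all(out == 77)

    def test_unknown_name_rejected(self, small_gray):
        with pytest.raises(ValueError):
            apply_reference_filter(small_gray, "median")


class TestFullReport:
    def test_all_fields_present(self, rng, small_gray):
        other = np.clip(
            small_gray.astype(int) + rng.integers(-10, 10, small_gray.shape), 0, 255
        ).astype(np.uint8)
        report = full_report(small_gray, other)
        d = report.to_dict()
        assert set(d) == {"mse", "psnr", "ssim", "ncc", "nae", "mae", "entropy", "eme"}
        assert all(np.isfinite(v) for v in d.values())
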