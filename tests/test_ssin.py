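import numpy as np
import pytest

from stacknorm import (
    SectionMeans,
    ThresholdRange,
    ZStack,
    analysis_mask,
    masked_mean,
    section_means,
    ssin_normalize,
)


def brute_force_ssin(soi, means, lo, hi, scale):
    """Independent per-pixel reference for ssin_normalize."""
    out = np.zeros(soi.shape, dtype=np.float64)
    for z in range(soi.shape[0]):
        for y in range(soi.shape[1]):
            for x in range(soi.shape[2]):
                p = float(soi[z, y, x])
                if p != 0 and lo <= p <= hi:
                    out[z, y, x] = p / means[z] * scale
    return out


class TestAnalysisMask:
    def test_threshold_and_zero_rules(self):
        section = np.array([[0, 10], [20, 30]])
        mask = analysis_mask(section, ThresholdRange(5, 25))
        np.testing.assert_array_equal(mask, [[False, True], [True, False]])

    def test_full_range_without_zeros_is_all_true(self, rng):
        section = rng.integers(1, 256, size=(5, 5))
        assert analysis_mask(section, ThresholdRange(0, 255)).all()

    def test_all_zero_section_gives_empty_mask(self):
        assert not analysis_mask(np.zeros((3, 3)), ThresholdRange(0, 255)).any()

    def test_bounds_are_inclusive(self):
        section = np.array([[5, 25]])
        assert analysis_mask(section, ThresholdRange(5, 25)).all()

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError, match="invalid threshold"):
            ThresholdRange(10, 5)


class TestMaskedMean:
    def test_thresholded_mean(self):
        section = np.array([[0, 10], [20, 30]])
        mask = analysis_mask(section, ThresholdRange(5, 25))
        assert masked_mean(section, mask) == 15.0

    def test_constant_section(self):
        section = np.full((4, 4), 42)
        assert masked_mean(section, np.ones((4, 4), bool)) == 42.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no analyzable pixels"):
            masked_mean(np.zeros((2, 2)), np.zeros((2, 2), bool))


class TestSectionMeans:
    def test_constant_sections(self):
        stack = ZStack(
            np.stack([np.full((2, 2), 100), np.full((2, 2), 50)]).astype(np.uint8),
            bit_depth=8,
        )
        np.testing.assert_allclose(section_means(stack).means, [100.0, 50.0])

    def test_zeros_excluded_from_mean(self):
        stack = ZStack(np.array([[[0, 0], [8, 4]]], np.uint8), bit_depth=8)
        assert section_means(stack).means[0] == 6.0

    def test_linear_in_intensity(self, rng):
        data = rng.integers(1, 80, size=(3, 4, 4), dtype=np.uint8)
        m1 = section_means(ZStack(data, bit_depth=8)).means
        m3 = section_means(ZStack(data * 3, bit_depth=8)).means
        np.testing.assert_allclose(m3, 3 * m1)

    def test_all_zero_section_names_index(self):
        data = np.ones((3, 2, 2), np.uint8)
        data[1] = 0
        with pytest.raises(ValueError, match="section 1"):
            section_means(ZStack(data, bit_depth=8))

    def test_nonpositive_means_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            SectionMeans([10.0, 0.0])


class TestSsinNormalize:
    def _stack(self, values):
        return ZStack(np.asarray(values, np.uint8), bit_depth=8)

    def test_raw_ratio_mode(self):
        soi = self._stack([np.full((2, 2), 80), np.full((2, 2), 40)])
        out = ssin_normalize(soi, SectionMeans([100.0, 50.0]), rescale_mode="none")
        np.testing.assert_allclose(out.data[0], 0.8)
        np.testing.assert_allclose(out.data[1], 0.8)

    def test_max_mean_rescale(self):
        soi = self._stack([np.full((2, 2), 80), np.full((2, 2), 40)])
        out = ssin_normalize(soi, SectionMeans([100.0, 50.0]))
        np.testing.assert_allclose(out.data, 80.0)

    def test_depth_flat_ns_changes_nothing(self, rng):
        data = rng.integers(0, 256, size=(3, 4, 4), dtype=np.uint8)
        soi = ZStack(data, bit_depth=8)
        thr = ThresholdRange(10, 200)
        out = ssin_normalize(soi, SectionMeans([70.0, 70.0, 70.0]), thr)
        expected = np.where(analysis_mask(data, thr), data, 0).astype(float)
        np.testing.assert_allclose(out.data, expected)

    def test_ns_scale_invariance(self, rng, small_stack):
        ns = ZStack(rng.integers(1, 200, size=(3, 4, 4), dtype=np.uint8), bit_depth=8)
        m = section_means(ns)
        m_scaled = SectionMeans(m.means * 2.5)
        out1 = ssin_normalize(small_stack, m)
        out2 = ssin_normalize(small_stack, m_scaled)
        np.testing.assert_allclose(out1.data, out2.data, rtol=1e-12)

    def test_masked_out_pixels_are_exactly_zero(self, small_stack):
        thr = ThresholdRange(50, 150)
        out = ssin_normalize(small_stack, SectionMeans([10.0, 20.0, 30.0]), thr)
        outside = ~analysis_mask(small_stack.data, thr)
        assert np.all(out.data[outside] == 0)
        assert np.all(out.data[~outside] > 0)

    def test_locality_under_pixel_permutation(self, rng, small_stack):
        means = SectionMeans([10.0, 20.0, 30.0])
        out = ssin_normalize(small_stack, means).data
        perm = rng.permutation(16)
        permuted = ZStack(
            small_stack.data.reshape(3, 16)[:, perm].reshape(3, 4, 4), bit_depth=8
        )
        out_perm = ssin_normalize(permuted, means).data
        np.testing.assert_array_equal(
            out.reshape(3, 16)[:, perm].reshape(3, 4, 4), out_perm
        )

    def test_section_count_mismatch_rejected(self, small_stack):
        with pytest.raises(ValueError, match="not aligned"):
            ssin_normalize(small_stack, SectionMeans([10.0, 20.0]))

    @pytest.mark.parametrize("mode", ["none", "max_mean"])
    def test_matches_brute_force_oracle(self, rng, mode):
        for _ in range(10):
            soi = ZStack(rng.integers(0, 256, (3, 4, 4), np.uint8), bit_depth=8)
            means = SectionMeans(rng.uniform(1, 200, size=3))
            lo, hi = sorted(rng.uniform(0, 255, size=2))
            out = ssin_normalize(soi, means, ThresholdRange(lo, hi), mode)
            scale = means.max if mode == "max_mean" else 1.0
            expected = brute_force_ssin(soi.data, means.means, lo, hi, scale)
            np.testing.assert_array_equal(out.data, expected)


class TestFlatnessRecovery:
    def test_proportional_attenuation_cancels_exactly(self):
        """Shared per-section attenuation leaves per-section post-SsIN
        means equal across depth for depth-flat base images."""
        rng = np.random.default_rng(7)
        # base values and factors chosen so a(z)*base is exactly integral
        base = rng.choice([40, 80, 120, 200], size=(6, 6)).astype(float)
        ns_base = rng.choice([40, 80, 120, 200], size=(6, 6)).astype(float)
        factors = np.array([1.0, 0.9, 0.75, 0.5, 0.3, 0.25])
        soi = ZStack((factors[:, None, None] * base).astype(np.uint8), bit_depth=8)
        ns = ZStack((factors[:, None, None] * ns_base).astype(np.uint8), bit_depth=8)
        out = ssin_normalize(soi, section_means(ns))
        sec_means = out.data.reshape(6, -1).mean(axis=1)
        np.testing.assert_allclose(sec_means, sec_means[0], rtol=1e-9)
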