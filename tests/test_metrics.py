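"""Adaptation metrics: contrast, gain, correlations, alignment, indices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import dstrfadapt as da
from dstrfadapt.metrics import (ADAPT_LATE, TransitionAlignedSeries,
                                _paired_t, adaptation_index,
                                align_to_transitions, dstrf_gain,
                                gain_change_index, index_ttest, lag_average,
                                noise_filtering_index,
                                noise_spectrum_correlation,
                                stimulus_contrast)
from dstrfadapt.session import NoiseSchedule, Segment


class TestStimulusContrast:
    def test_constant_segment_floored(self):
        assert stimulus_contrast(np.full((100, 23), 3.0)) == -120.0

    def test_half_zero_half_two(self):
        v = np.zeros((10, 2))
        v[5:] = 2.0
        assert np.isclose(stimulus_contrast(v), 0.0)   # sd 1 -> 0 dB

    def test_doubling_adds_six_db(self):
        rng = np.random.default_rng(0)
        v = np.abs(rng.standard_normal((50, 23)))
        assert np.isclose(stimulus_contrast(2 * v) - stimulus_contrast(v),
                          20 * np.log10(2))


class TestDstrfGain:
    def test_zero_frame(self):
        for region in ("full", "excitatory", "inhibitory"):
            assert dstrf_gain(np.zeros((4, 4)), region) == 0.0

    def test_two_by_two_example(self):
        f = np.array([[1.0, -1.0], [1.0, -1.0]])
        assert np.isclose(dstrf_gain(f, "full"), 1.0)
        assert np.isclose(dstrf_gain(f, "excitatory"), 0.5)
        assert np.isclose(dstrf_gain(f, "inhibitory"), 0.5)

    @given(st.floats(-5, 5, allow_nan=False).filter(lambda c: abs(c) > 1e-6))
    @settings(max_examples=25, deadline=None)
    def test_homogeneity(self, c):
        rng = np.random.default_rng(1)
        f = rng.standard_normal((3, 4))
        assert np.isclose(dstrf_gain(c * f), abs(c) * dstrf_gain(f))

    def test_region_profiles_sum_to_full(self):
        rng = np.random.default_rng(2)
        f = rng.standard_normal((23, 65))
        np.testing.assert_allclose(
            lag_average(f, "excitatory") + lag_average(f, "inhibitory"),
            lag_average(f, "full"), atol=1e-12)


class TestNoiseSpectrumCorrelation:
    def test_proportional_profile(self):
        target = np.abs(np.random.default_rng(0).standard_normal(23))
        frame = np.tile(3 * target[:, None], (1, 65))
        assert np.isclose(noise_spectrum_correlation(frame, target), 1.0)
        assert np.isclose(noise_spectrum_correlation(-frame, target), -1.0)

    def test_orthogonalized_profile(self):
        rng = np.random.default_rng(3)
        target = rng.standard_normal(23)
        prof = rng.standard_normal(23)
        tc = target - target.mean()
        pc = prof - prof.mean()
        pc -= (pc @ tc) / (tc @ tc) * tc     # Gram-Schmidt vs centered target
        r = noise_spectrum_correlation(pc[:, None] * np.ones((1, 5)), target)
        assert abs(r) < 1e-10

    def test_constant_profile_undefined(self):
        assert np.isnan(noise_spectrum_correlation(np.ones((23, 5)),
                                                   np.arange(23.0)))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            noise_spectrum_correlation(np.ones((23, 5)), np.ones(10))


def _schedule(*conds, seg=3.0, t0=0.0):
    segs, t = [], t0
    for c in conds:
        segs.append(Segment(t, t + seg, c))
        t += seg
    return NoiseSchedule(segs, [t0, t])


class TestAlignment:
    def test_counts_with_filter(self):
        sch = _schedule("clean", "bar", "clean", "city", seg=4.0)
        times = np.arange(1600) / 100.0
        tc = np.random.default_rng(0).standard_normal(1600)
        aligned = align_to_transitions(
            tc, times, sch, lambda a, b: a == "clean" and b != "clean",
            pre_s=0.5, post_s=1.15)
        assert aligned.n_transitions == 2
        assert [t[2] for t in aligned.transitions] == ["bar", "city"]
        assert aligned.values.shape == (2, 165)

    def test_noise_to_noise_excluded_by_filter(self):
        sch = _schedule("bar", "city", "jet", seg=4.0)
        times = np.arange(1200) / 100.0
        tc = np.zeros(1200)
        f = lambda a, b: (a == "clean") != (b == "clean")
        aligned = align_to_transitions(tc, times, sch, f)
        assert aligned.empty

    def test_window_grid(self):
        sch = _schedule("clean", "jet", "clean", seg=6.0)
        times = np.arange(1800) / 100.0
        aligned = align_to_transitions(np.zeros(1800), times, sch,
                                       pre_s=0.5, post_s=1.15)
        assert aligned.values.shape[1] == int((0.5 + 1.15) * 100)
        assert np.isclose(aligned.rel_times[0], -0.5)

    def test_truncated_windows_excluded(self):
        # 1-s middle segment cannot contain a 1.15-s post window
        sch = NoiseSchedule([Segment(0, 3, "clean"), Segment(3, 4, "bar"),
                             Segment(4, 8, "clean")], [0, 8])
        times = np.arange(800) / 100.0
        aligned = align_to_transitions(
            np.zeros(800), times, sch,
            lambda a, b: b != "clean", pre_s=0.5, post_s=1.15)
        assert aligned.empty


class TestIndexTtest:
    def test_textbook_example(self):
        """pre [1,2,3], post [2,4,3]: differences [1,2,0] -> t = sqrt(3)."""
        t = index_ttest(np.array([1.0, 2, 3]), np.array([2.0, 4, 3]))
        assert np.isclose(t, np.sqrt(3.0))

    def test_equal_windows_give_zero(self):
        x = np.random.default_rng(0).standard_normal(50)
        assert index_ttest(x, x) == 0.0

    def test_antisymmetric(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        assert np.isclose(index_ttest(a, b), -index_ttest(b, a))

    def test_scipy_agreement(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        assert np.isclose(index_ttest(a, b), stats.ttest_rel(b, a).statistic)

    def test_degenerate_capped(self):
        t, flag = _paired_t(np.zeros(10), np.ones(10))
        assert t == 1e6 and flag == "degenerate"

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            index_ttest(np.zeros(3), np.zeros(4))

    @given(st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_shift_invariance(self, c):
        rng = np.random.default_rng(3)
        a, b = rng.standard_normal(30), rng.standard_normal(30)
        assert np.isclose(index_ttest(a + c, b + c), index_ttest(a, b))


def _aligned_from_course(course, rate=100.0, pre_s=0.5):
    n = len(course)
    rel = (np.arange(n) - int(pre_s * rate)) / rate
    return TransitionAlignedSeries(course[None, :], rel, [(0.0, "clean",
                                                           "jet")],
                                   (pre_s, (n / rate) - pre_s))


class TestWindowedIndices:
    def test_flat_course_zero(self):
        aligned = _aligned_from_course(np.ones(165))
        assert gain_change_index(aligned) == 0.0
        assert noise_filtering_index(aligned) == 0.0

    def test_gain_drop_negative_index(self):
        course = np.concatenate([np.ones(50), 0.4 * np.ones(115)])
        course += 0.01 * np.sin(np.arange(165))
        assert gain_change_index(_aligned_from_course(course)) < 0

    def test_noise_filtering_sign_flip(self):
        # correlation drops after transition -> positive filtering index
        course = np.concatenate([0.5 * np.ones(50), -0.2 * np.ones(115)])
        course += 0.01 * np.cos(np.arange(165))
        assert noise_filtering_index(_aligned_from_course(course)) > 0


class TestAdaptationIndex:
    def _aligned(self, course):
        rel = np.arange(len(course)) / 100.0
        return TransitionAlignedSeries(course[None], rel,
                                       [(0.0, "clean", "jet")],
                                       (0.0, ADAPT_LATE[1]))

    def test_flat_response_zero(self):
        assert self._aligned(np.ones(270)).values.shape == (1, 270)
        assert adaptation_index(self._aligned(np.ones(270))) == 0.0

    def test_transient_positive_and_monotone_in_amplitude(self):
        t = np.arange(270) / 100.0
        jitter = 0.01 * np.sin(37 * t)
        small = adaptation_index(self._aligned(
            1.0 * np.exp(-t / 0.3) + jitter))
        large = adaptation_index(self._aligned(
            3.0 * np.exp(-t / 0.3) + jitter))
        assert 0 < small < large

    def test_windows_have_seventy_samples(self):
        rel = np.arange(270) / 100.0
        from dstrfadapt.metrics import ADAPT_EARLY, _window_slices

        assert _window_slices(rel, ADAPT_EARLY).sum() == 70
        assert _window_slices(rel, ADAPT_LATE).sum() == 70
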