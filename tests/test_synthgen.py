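"""Stimulus and response generator: spectra, SNR, schedule, determinism."""

import numpy as np
import pytest

import dstrfadapt as da
from dstrfadapt.session import NOISE_CONDITIONS
from dstrfadapt.synthgen import (_linear_drive, generate_noise, local_contrast,
                                 speech_spectrum)


class TestNoiseClasses:
    def test_three_distinct_classes(self):
        specs = da.make_noise_classes(seed=0)
        assert [s.label for s in specs] == ["bar", "city", "jet"]
        for s in specs:
            assert np.isclose(s.mean_spectrum.sum(), 1.0)
        for i in range(3):
            for j in range(i + 1, 3):
                r = np.corrcoef(specs[i].mean_spectrum,
                                specs[j].mean_spectrum)[0, 1]
                assert r < 0.8

    def test_jet_is_high_frequency(self):
        jet = da.make_noise_classes(seed=0)[2].mean_spectrum
        top = int(np.ceil(2 * len(jet) / 3))
        assert jet[top:].sum() > 0.7

    def test_bar_overlaps_speech_more_than_jet(self):
        specs = da.make_noise_classes(seed=0)
        sp = speech_spectrum()
        r_bar = np.corrcoef(specs[0].mean_spectrum, sp)[0, 1]
        r_jet = np.corrcoef(specs[2].mean_spectrum, sp)[0, 1]
        assert r_bar > r_jet

    def test_deterministic(self):
        a = da.make_noise_classes(seed=0)
        b = da.make_noise_classes(seed=0)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.mean_spectrum, y.mean_spectrum)


class TestForeground:
    def test_shape_and_nonnegative(self):
        sp = da.generate_foreground(10.0, seed=1)
        assert sp.values.shape == (1000, 23)
        assert (sp.values >= 0).all()

    def test_modulation_spectrum_peaks_at_syllabic_rate(self):
        sp = da.generate_foreground(60.0, seed=2)
        env = sp.values.sum(axis=1)
        env = env - env.mean()
        freqs = np.fft.rfftfreq(len(env), d=0.01)
        power = np.abs(np.fft.rfft(env)) ** 2
        band = (freqs >= 0.5) & (freqs <= 20.0)
        peak = freqs[band][np.argmax(power[band])]
        assert 2.0 <= peak <= 8.0

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            da.generate_foreground(0.0, seed=0)


class TestMixAtSnr:
    def test_equal_power_zero_snr(self):
        rng = np.random.default_rng(0)
        a = da.Spectrogram(np.abs(rng.standard_normal((500, 23))))
        out = da.mix_at_snr(a, a, snr_db=0.0)
        np.testing.assert_allclose(out.values, 2 * a.values)

    @pytest.mark.parametrize("snr_db", [0.0, 6.0, -3.0])
    def test_realized_snr(self, snr_db):
        rng = np.random.default_rng(1)
        fore = da.Spectrogram(np.abs(rng.standard_normal((400, 23))))
        back = da.Spectrogram(2 * np.abs(rng.standard_normal((400, 23))))
        mixed = da.mix_at_snr(fore, back, snr_db)
        resid = mixed.values - fore.values
        realized = 10 * np.log10(np.mean(fore.values ** 2)
                                 / np.mean(resid ** 2))
        assert abs(realized - snr_db) < 0.1

    def test_zero_background_errors(self):
        fore = da.Spectrogram(np.ones((100, 23)))
        back = da.Spectrogram(np.zeros((100, 23)))
        with pytest.raises(ValueError):
            da.mix_at_snr(fore, back, 6.0)


class TestBuildSession:
    def test_schedule_tiles_and_durations(self, built_stimulus):
        sch = built_stimulus.schedule
        durs = [s.duration for s in sch.segments]
        assert all(np.isclose(d, 3.0) or np.isclose(d, 6.0) for d in durs)
        assert np.isclose(sum(durs), 3 * 24.0)
        assert np.isclose(sch.start, 12.0)
        for a, b in zip(sch.segments, sch.segments[1:]):
            assert a.condition != b.condition
        assert len(sch.transitions()) == len(sch.segments) - 1

    def test_total_duration_includes_lead_in(self, built_stimulus):
        stim = built_stimulus.stimulus
        assert stim.n_samples == int((12.0 + 3 * 24.0) * 100)
        # lead-in is silent
        assert np.all(stim.values[:1200] == 0)

    def test_all_conditions_drawn_and_balanced(self):
        built = da.build_session(n_blocks=18, block_duration=60.0, seed=0)
        exposure = {}
        for s in built.schedule.segments:
            exposure[s.condition] = exposure.get(s.condition, 0) + s.duration
        assert set(exposure) == {"clean", *NOISE_CONDITIONS}
        mean = np.mean(list(exposure.values()))
        for v in exposure.values():
            assert abs(v - mean) / mean < 0.2

    def test_segment_snr_conserved(self, built_stimulus):
        for seg in built_stimulus.schedule.segments:
            if seg.condition == "clean":
                continue
            f = built_stimulus.foreground.slice_time(seg.start, seg.end)
            m = built_stimulus.stimulus.slice_time(seg.start, seg.end)
            noise = m.values - f.values
            snr = 10 * np.log10(np.mean(f.values ** 2)
                                / np.mean(noise ** 2))
            assert abs(snr - 6.0) < 0.1

    def test_deterministic(self):
        a = da.build_session(n_blocks=2, block_duration=12.0, seed=3,
                             lead_in=6.0)
        b = da.build_session(n_blocks=2, block_duration=12.0, seed=3,
                             lead_in=6.0)
        np.testing.assert_array_equal(a.stimulus.values, b.stimulus.values)
        assert a.schedule.segments == b.schedule.segments

    def test_too_few_blocks(self):
        with pytest.raises(ValueError):
            da.build_session(n_blocks=1)


class TestSimulateResponses:
    def test_static_linear_matches_convolution_oracle(self, linear_session,
                                                      linear_session_filters):
        sess = linear_session
        stim = sess.stimulus
        filt = linear_session_filters[0]
        drive = _linear_drive(stim.values, filt)
        task = stim.times >= sess.schedule.start
        drive = drive + 1.5 * drive[task].std()
        r = np.logaddexp(0.0, drive)
        base = sess.responses.baseline_slice()
        expected = r - r[base].mean()  # noiseless baseline: centered only
        np.testing.assert_allclose(sess.responses.values[0], expected,
                                   atol=1e-9)

    def test_baseline_normalization_exact(self):
        sess = da.make_session(n_blocks=2, block_duration=12.0, seed=9,
                               n_electrodes=3, encoder_kind="static_linear",
                               output_noise_sd=0.5, lead_in=10.0)
        base = sess.responses.values[:, sess.responses.baseline_slice()]
        np.testing.assert_allclose(base.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(base.std(axis=1), 1.0, atol=1e-9)

    def test_gain_adaptive_constant_condition_is_scaled_static(self):
        """With constant background the contrast is stationary, so the
        adaptive gain reduces to a near-constant scale on the rectified
        drive."""
        fore = da.generate_foreground(30.0, seed=4)
        sch = da.NoiseSchedule(
            [da.Segment(5.0, 35.0, "clean")], [5.0, 35.0])
        stim = da.Spectrogram(
            np.vstack([np.zeros((500, 23)), fore.values]))
        filt = da.make_base_filter(0)
        static = da.GroundTruthEncoder("static_linear", filt,
                                       output_noise_sd=0.0)
        adap = da.GroundTruthEncoder("gain_adaptive", filt, gain_alpha=0.5,
                                     output_noise_sd=0.0)
        rs = da.simulate_responses(stim, sch, [static, adap], seed=0,
                                   lead_in=5.0)
        task = stim.times >= 10.0  # skip the contrast build-up
        r = np.corrcoef(rs.values[0][task], rs.values[1][task])[0, 1]
        assert r > 0.98

    def test_gain_drops_when_contrast_rises(self):
        """A clean -> noise step raises trailing-window contrast, so the
        adaptive gain falls by about g(c_post)/g(c_pre)."""
        rng = np.random.default_rng(0)
        n = 4000
        low = np.abs(0.3 * rng.standard_normal((n // 2, 23)))
        high = np.abs(2.0 * rng.standard_normal((n // 2, 23)))
        stim = da.Spectrogram(np.vstack([low, high]))
        sch = da.NoiseSchedule(
            [da.Segment(0.0, 20.0, "clean"), da.Segment(20.0, 40.0, "jet")],
            [0.0, 40.0])
        filt = da.make_base_filter(1)
        enc = da.GroundTruthEncoder("gain_adaptive", filt, gain_alpha=0.5,
                                    tau_adapt=0.2, output_noise_sd=0.0,
                                    drive_offset_sd=3.0)
        from dstrfadapt.synthgen import effective_filter_timecourse

        idx = np.array([1500, 3500])  # steady states pre/post
        filters = effective_filter_timecourse(enc, stim, sch, idx)
        g_pre = np.linalg.norm(filters[0])
        g_post = np.linalg.norm(filters[1])
        c = local_contrast(stim, 1.0)
        expected = ((c[3500] + enc.gain_c0) / (c[1500] + enc.gain_c0)) ** -0.5
        assert g_post < g_pre
        assert np.isclose(g_post / g_pre, expected, rtol=0.05)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            da.GroundTruthEncoder("bogus", np.zeros((23, 65)))

    def test_determinism(self, built_stimulus):
        enc = [da.GroundTruthEncoder("static_linear", da.make_base_filter(0),
                                     output_noise_sd=0.2)]
        a = da.simulate_responses(built_stimulus.stimulus,
                                  built_stimulus.schedule, enc, seed=1)
        b = da.simulate_responses(built_stimulus.stimulus,
                                  built_stimulus.schedule, enc, seed=1)
        np.testing.assert_array_equal(a.values, b.values)


class TestNoiseFilteringGenerator:
    def test_effective_filter_develops_inhibition_at_noise_band(self,
                                                                built_stimulus):
        built = built_stimulus
        enc = da.GroundTruthEncoder("noise_filtering", da.make_base_filter(2),
                                    suppression_depth=1.5, tau_adapt=0.3,
                                    output_noise_sd=0.0)
        from dstrfadapt.synthgen import effective_filter_timecourse

        # find a transition into noise and compare 1 s after vs just before
        for t0, frm, to in built.schedule.transitions():
            if frm == "clean" and to != "clean":
                break
        i0 = int(round(t0 * 100))
        filters = effective_filter_timecourse(
            enc, built.stimulus, built.schedule,
            np.array([i0 - 5, i0 + 100]),
            noise_classes=built.noise_classes)
        spec = next(s.mean_spectrum for s in built.noise_classes
                    if s.label == to)
        peak_band = int(np.argmax(spec))
        before = filters[0][peak_band].mean()
        after = filters[1][peak_band].mean()
        assert after < before
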