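"""Synthetic motion, sweep rendering and the band reference channel."""
import numpy as np
import pytest

import respiradar as rr
from respiradar import TrialSchedule, synth
from respiradar.features import estimate_respiratory_cycle

from conftest import noiseless_profile

RESP, HOLD, SWAL = rr.RESP, rr.HOLD, rr.SWAL


def _interval_slice(trace, interval):
    i0 = int(round(interval.start / trace.frame_interval))
    i1 = int(round(interval.end / trace.frame_interval))
    return trace.values[i0:i1]


class TestGenerateMotion:
    def test_fixed_seed_is_bit_identical(self):
        profile = rr.SubjectProfile(seed=5)
        schedule = TrialSchedule.default(1.0)
        t1, a1 = rr.generate_motion(profile, schedule)
        t2, a2 = rr.generate_motion(profile, schedule)
        assert np.array_equal(t1.values, t2.values)
        assert a1.intervals == a2.intervals

    def test_pure_breathing_period_recovered_by_autocorrelation(self):
        profile = noiseless_profile(breathing_period=4.0)
        trace, _ = rr.generate_motion(profile, TrialSchedule(((RESP, 30.0),)))
        period = estimate_respiratory_cycle(trace)
        assert period == pytest.approx(4.0, abs=0.1)

    def test_pauses_are_flat_plateaus(self):
        profile = noiseless_profile(seed=2)
        trace, annotation = rr.generate_motion(profile, TrialSchedule.default(1.0))
        for iv in annotation.intervals:
            if iv.label in (HOLD, SWAL):
                seg = _interval_slice(trace, iv)
                limit = 0.05 * profile.breathing_amplitude
                assert np.abs(np.diff(seg)).max() < limit
                assert np.abs(np.diff(seg)).max() == 0.0  # exactly flat pre-noise

    def test_trace_is_continuous_at_pause_boundaries(self):
        profile = noiseless_profile(seed=4, period_variability=0.1,
                                    amplitude_variability=0.1)
        trace, _ = rr.generate_motion(profile, TrialSchedule.default(0.5))
        # largest sample-to-sample jump stays below the breathing slope scale
        max_breath_step = (np.pi * profile.breathing_amplitude * 1.4
                           / (2 * 0.33 * 2.5) * trace.frame_interval)
        assert np.abs(np.diff(trace.values)).max() < 2 * max_breath_step

    def test_hold_annotation_shifted_by_instruction_delay(self):
        profile = noiseless_profile()
        schedule = TrialSchedule.default(1.0)  # hold instructed at 10-15 s
        _, annotation = rr.generate_motion(profile, schedule)
        (hold,) = annotation.with_label(HOLD)
        assert hold.start == pytest.approx(10.5)
        assert hold.end == pytest.approx(15.5)  # duration preserved

    @pytest.mark.parametrize("period", [2.5, 5.0])
    def test_breathing_power_in_respiratory_band(self, period):
        profile = noiseless_profile(breathing_period=period)
        trace, annotation = rr.generate_motion(profile,
                                               TrialSchedule(((RESP, 40.0),)))
        seg = _interval_slice(trace, annotation.intervals[0])
        spec = np.abs(np.fft.rfft(seg - seg.mean()))
        freqs = np.fft.rfftfreq(seg.size, d=trace.frame_interval)
        peak = freqs[np.argmax(spec)]
        assert 0.2 - 1e-6 <= peak <= 0.4 + 1e-6

    def test_swallow_lands_mid_expiration_by_default(self):
        profile = noiseless_profile(seed=9)
        trace, annotation = rr.generate_motion(profile, TrialSchedule.default(1.0))
        (swal,) = annotation.with_label(SWAL)
        i0 = int(round(swal.start / trace.frame_interval))
        # mid-expiration: near the centre of the excursion, rising beforehand
        plateau = trace.values[i0]
        assert abs(plateau) < 0.3 * profile.breathing_amplitude
        assert trace.values[i0 - 1] - trace.values[i0 - 20] > 0

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            TrialSchedule(((SWAL, 2.5), (RESP, 10.0)))  # swallow too long
        with pytest.raises(ValueError):
            TrialSchedule(((RESP, 3.0),))  # shorter than one window
        with pytest.raises(ValueError):
            TrialSchedule(())


class TestRenderSweeps:
    def test_constant_distance_peaks_at_expected_bin(self, config):
        profile = noiseless_profile(baseline_distance=0.35)
        trace = rr.DisplacementTrace(np.zeros(50), config.frame_interval)
        sweeps = rr.render_sweeps(trace, config, profile, amplitude_noise_sd=0.0)
        assert np.all(np.argmax(sweeps.amplitude, axis=1) == 150)

    def test_phase_matches_forward_formula_without_noise(self, config):
        profile = noiseless_profile(baseline_distance=0.4)
        values = np.linspace(0.0, 2.0, 80)  # mm
        trace = rr.DisplacementTrace(values, config.frame_interval)
        sweeps = rr.render_sweeps(trace, config, profile, amplitude_noise_sd=0.0)
        d = profile.baseline_distance + values / 1000.0
        expected = np.mod(4 * np.pi * config.center_frequency * d
                          / config.speed_of_light, 2 * np.pi)
        peak = np.argmax(sweeps.amplitude, axis=1)
        got = sweeps.phase[np.arange(80), peak]
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_phases_wrapped_into_principal_range(self, config):
        profile = rr.SubjectProfile(seed=3)
        trace, _ = rr.generate_motion(profile, TrialSchedule(((RESP, 5.0),)))
        sweeps = rr.render_sweeps(trace, config, profile)
        assert sweeps.phase.min() >= 0.0
        assert sweeps.phase.max() < 2 * np.pi

    def test_rejects_motion_leaving_the_swept_range(self, config):
        profile = noiseless_profile(baseline_distance=0.65)
        trace = rr.DisplacementTrace(np.linspace(0.0, 60.0, 40),
                                     config.frame_interval)
        with pytest.raises(ValueError, match="range"):
            rr.render_sweeps(trace, config, profile)

    def test_same_seed_renders_identically(self, config):
        profile = rr.SubjectProfile(seed=8)
        trace, _ = rr.generate_motion(profile, TrialSchedule(((RESP, 5.0),)))
        s1 = rr.render_sweeps(trace, config, profile)
        s2 = rr.render_sweeps(trace, config, profile)
        assert np.array_equal(s1.amplitude, s2.amplitude)
        assert np.array_equal(s1.phase, s2.phase)


class TestBandSignal:
    def test_unit_gain_zero_noise_is_identity(self):
        profile = noiseless_profile()
        trace, _ = rr.generate_motion(profile, TrialSchedule(((RESP, 10.0),)))
        out = rr.render_band_signal(trace, gain=1.0, noise_sd=0.0)
        np.testing.assert_array_equal(out, trace.values)

    def test_negative_gain_flips_correlation(self):
        profile = noiseless_profile()
        trace, _ = rr.generate_motion(profile, TrialSchedule(((RESP, 10.0),)))
        out = rr.render_band_signal(trace, gain=-1.0, noise_sd=0.0)
        assert np.corrcoef(out, trace.values)[0, 1] == pytest.approx(-1.0)

    def test_snr10_keeps_zero_lag_correlation_high(self):
        from respiradar.validation import cross_correlation

        profile = noiseless_profile(seed=6)
        trace, _ = rr.generate_motion(profile, TrialSchedule(((RESP, 30.0),)))
        noise_sd = float(np.std(trace.values)) / np.sqrt(10.0)
        out = rr.render_band_signal(trace, noise_sd=noise_sd, seed=1)
        assert cross_correlation(out, trace.values) > 0.95


class TestCohortSimulation:
    def test_class_imbalance_ordering(self):
        recordings = rr.simulate_recordings(n_subjects=3, trials_per_subject=2,
                                            seed=1, through_radar=False)
        dataset = rr.build_dataset(recordings)
        counts = dataset.class_counts
        assert counts[RESP] > counts[HOLD] > counts[SWAL]

    def test_profiles_vary_across_subjects_not_trials(self):
        recordings = rr.simulate_recordings(n_subjects=2, trials_per_subject=2,
                                            seed=1, through_radar=False)
        (t_a1, _, s_a1), (t_a2, _, _), (t_b1, _, s_b1), _ = recordings
        assert s_a1 != s_b1
        # same subject, different trial noise: traces differ but correlate
        assert not np.array_equal(t_a1.values, t_a2.values)
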