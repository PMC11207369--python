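"""The four designed feature families and respiratory-cycle estimation."""
import numpy as np
import pytest

import respiradar as rr
from respiradar import TrialSchedule
from respiradar.features import (
    autocorrelation_features,
    designed_feature_names,
    designed_features,
    estimate_respiratory_cycle,
    fft_features,
    general_features,
    histogram_features,
    movement_range_features,
    prune_constant_features,
)
from respiradar.segmentation import slide_windows, label_window

from conftest import noiseless_profile, sine_window


class TestMovementRange:
    def test_constant_window_all_zero(self):
        np.testing.assert_array_equal(movement_range_features(np.full(400, 3.3)),
                                      np.zeros(10))

    def test_linear_ramp_spans(self):
        ramp = np.linspace(0.0, 1.0, 400)
        spans = movement_range_features(ramp)
        # quantile oracle: span_k of a uniform ramp is ~0.1 k
        np.testing.assert_allclose(spans, 0.1 * np.arange(1, 11), atol=0.01)

    def test_sine_full_span_is_peak_to_peak(self):
        x = sine_window(period_s=4.0, amplitude=2.5)
        assert movement_range_features(x)[-1] == pytest.approx(5.0, rel=0.01)

    def test_nonnegative_and_nondecreasing(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            spans = movement_range_features(rng.normal(size=400))
            assert spans[0] >= 0
            assert np.all(np.diff(spans) >= -1e-12)


class TestAutocorrelation:
    def test_four_second_sine_peaks_at_its_period(self):
        x = sine_window(period_s=4.0, n=800)
        ac = autocorrelation_features(x)
        lags_s = 0.4 * np.arange(1, 11)
        long_lags = lags_s >= 2.0
        assert np.argmax(ac[long_lags]) == np.flatnonzero(lags_s == 4.0)[0] \
            - np.flatnonzero(long_lags)[0]

    def test_white_noise_has_small_autocorrelation(self):
        rng = np.random.default_rng(7)
        ac = autocorrelation_features(rng.normal(size=400))
        assert np.all(np.abs(ac) < 0.2)

    def test_constant_window_all_zero(self):
        np.testing.assert_array_equal(
            autocorrelation_features(np.full(400, 1.0)), np.zeros(10))

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            ac = autocorrelation_features(rng.normal(size=400))
            assert np.all(np.abs(ac) <= 1.0)

    def test_lag_equal_to_window_length_is_zero(self):
        ac = autocorrelation_features(sine_window(n=400))
        assert ac[-1] == 0.0  # 4 s lag on a 4 s window: zero-padding rule


class TestFft:
    @pytest.mark.parametrize("period_s,dominant_bin", [(4.0, 0), (2.0, 1)])
    def test_integer_period_sine_concentrates_in_one_bin(self, period_s,
                                                         dominant_bin):
        mags = fft_features(sine_window(period_s=period_s))
        others = np.delete(mags, dominant_bin)
        assert mags[dominant_bin] > 10 * others.max()

    def test_constant_window_all_zero(self):
        np.testing.assert_allclose(fft_features(np.full(400, 2.0)),
                                   np.zeros(10), atol=1e-10)

    def test_magnitudes_nonnegative(self):
        rng = np.random.default_rng(5)
        assert np.all(fft_features(rng.normal(size=400)) >= 0)


class TestHistogram:
    def test_uniform_ramp_spreads_evenly(self):
        h = histogram_features(np.linspace(0.0, 1.0, 400))
        np.testing.assert_allclose(h, 0.1, atol=0.01)

    def test_constant_window_degenerate_rule(self):
        h = histogram_features(np.full(400, 7.0))
        np.testing.assert_array_equal(h, [1.0] + [0.0] * 9)

    def test_sine_window_is_u_shaped(self):
        h = histogram_features(sine_window(period_s=4.0))
        interior = h[1:-1]
        top_two_interior = np.sort(interior)[-2:].sum()
        assert h[0] + h[-1] > top_two_interior

    def test_mass_conserved_and_max_in_top_bin(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=400)
        h = histogram_features(x)
        assert h.sum() == pytest.approx(1.0)
        assert h[-1] >= 1 / 400  # the maximum sample lands in the last bin


class TestDesignedVector:
    def test_length_and_family_layout(self):
        x = sine_window()
        vec = designed_features(x)
        assert vec.shape == (40,)
        names = designed_feature_names()
        assert len(names) == 40
        assert names[0] == "range_01" and names[10] == "ac_01"
        assert names[20] == "fft_01" and names[39] == "hist_10"
        np.testing.assert_array_equal(vec[:10], movement_range_features(x))
        np.testing.assert_array_equal(vec[30:], histogram_features(x))

    def test_constant_window(self):
        vec = designed_features(np.full(400, 1.0))
        np.testing.assert_allclose(vec[:30], 0.0, atol=1e-10)
        np.testing.assert_array_equal(vec[30:], [1.0] + [0.0] * 9)

    def test_deterministic(self):
        x = sine_window(phase=0.3)
        np.testing.assert_array_equal(designed_features(x),
                                      designed_features(x.copy()))

    def test_amplitude_scaling_equivariance(self):
        x = sine_window(period_s=3.0, amplitude=2.0, phase=0.4) \
            + 0.05 * np.random.default_rng(2).normal(size=400)
        a = 3.7
        v1, v2 = designed_features(x), designed_features(a * x)
        np.testing.assert_allclose(v2[:10], a * v1[:10], rtol=1e-9)   # range
        np.testing.assert_allclose(v2[20:30], a * v1[20:30], rtol=1e-9)  # fft
        np.testing.assert_allclose(v2[10:20], v1[10:20], rtol=1e-9)   # autocorr
        np.testing.assert_allclose(v2[30:], v1[30:], atol=1e-12)      # hist

    def test_hold_windows_have_collapsed_movement_range(self):
        profile = rr.SubjectProfile(seed=21)
        trace, ann = rr.generate_motion(profile, TrialSchedule.default(1.0))
        (hold,) = ann.with_label(rr.HOLD)
        spans = {"hold": [], "resp": []}
        for w in slide_windows(trace):
            if w.start_time >= hold.start and w.end_time <= hold.end:
                spans["hold"].append(movement_range_features(w.values)[-1])
            elif label_window(w, ann) == rr.RESP:
                spans["resp"].append(movement_range_features(w.values)[-1])
        assert spans["hold"] and spans["resp"]
        assert max(spans["hold"]) < 0.25 * np.median(spans["resp"])


class TestGeneralFeatures:
    def test_finite_even_for_constant_window(self):
        feats = general_features(np.full(400, 4.0))
        assert np.all(np.isfinite(feats.to_numpy()))

    def test_deterministic(self):
        x = sine_window(phase=1.1)
        assert general_features(x).equals(general_features(x.copy()))

    def test_pruning_removes_constant_columns(self):
        import pandas as pd

        windows = [sine_window(phase=p) for p in (0.0, 0.5, 1.0)] \
            + [np.full(400, 2.0)]
        table = pd.DataFrame([general_features(w) for w in windows])
        pruned = prune_constant_features(table)
        assert pruned.shape[1] < table.shape[1]
        assert all(pruned.nunique(axis=0) > 1)


class TestRespiratoryCycle:
    @pytest.mark.parametrize("period", [2.5, 4.0])
    def test_sine_period_recovered(self, period):
        trace = rr.DisplacementTrace(sine_window(period_s=period, n=3000), 0.01)
        assert estimate_respiratory_cycle(trace) == pytest.approx(period,
                                                                  abs=0.1)

    def test_white_noise_is_indeterminate(self):
        rng = np.random.default_rng(4)
        trace = rr.DisplacementTrace(rng.normal(size=2000), 0.01)
        assert estimate_respiratory_cycle(trace) is None

    def test_short_trace_rejected(self):
        trace = rr.DisplacementTrace(sine_window(n=500), 0.01)
        with pytest.raises(ValueError):
            estimate_respiratory_cycle(trace)

    def test_cohort_periods_match_profiles(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            profile = rr.SubjectProfile.random(rng)
            profile = noiseless_profile(
                breathing_period=profile.breathing_period,
                breathing_amplitude=profile.breathing_amplitude,
                seed=profile.seed,
            )
            trace, _ = rr.generate_motion(profile,
                                          TrialSchedule(((rr.RESP, 30.0),)))
            est = estimate_respiratory_cycle(trace)
            assert est == pytest.approx(profile.breathing_period, abs=0.15)
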