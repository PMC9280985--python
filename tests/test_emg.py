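"""EMG processing: rectification, background, MVC normalization, cycles,
binning and ensemble statistics."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neckcore.emg_processing import (
    activation_ratio,
    bin_profile,
    ensemble_average,
    estimate_background,
    integrate_cycle,
    mvc_reference,
    normalize,
    rectify,
    segment_cycles,
    subtract_background,
)
from neckcore.signal_model import ChannelTrace, EventKind, EventSet, Units, ValidationError
from neckcore.synthetic_data import generate_emg_channel


def _trace(samples, fs=1000.0):
    return ChannelTrace(np.asarray(samples, dtype=float), fs, Units.VOLTS)


class TestRectify:
    def test_absolute_value(self):
        out = rectify(_trace([-1.0, 2.0, -3.0]))
        np.testing.assert_array_equal(out.samples, [1.0, 2.0, 3.0])

    def test_zero_fixed_point_and_idempotence(self):
        zero = rectify(_trace([0.0, 0.0]))
        np.testing.assert_array_equal(zero.samples, 0.0)
        x = _trace(np.sin(np.arange(50)))
        np.testing.assert_array_equal(rectify(rectify(x)).samples, rectify(x).samples)

    def test_rejects_non_emg_units(self):
        with pytest.raises(ValidationError):
            rectify(ChannelTrace(np.ones(5), 100.0, Units.NEWTONS))


class TestBackground:
    def test_constant_trace(self):
        assert estimate_background(_trace(np.full(600, 0.2))) == pytest.approx(0.2)

    def test_mean_of_lowest_500_points(self):
        samples = np.concatenate([np.full(500, 0.1), np.full(300, 1.0)])
        rng = np.random.default_rng(0)
        assert estimate_background(_trace(rng.permutation(samples))) == pytest.approx(0.1)

    def test_short_recording_rejected(self):
        with pytest.raises(ValidationError):
            estimate_background(_trace(np.ones(499)))

    def test_subtraction_clips_at_zero(self):
        out = subtract_background(_trace([0.5, 0.1]), 0.2)
        np.testing.assert_allclose(out.samples, [0.3, 0.0])

    def test_exact_cancellation_and_identity(self):
        x = _trace(np.full(10, 0.7))
        np.testing.assert_allclose(subtract_background(x, 0.7).samples, 0.0)
        np.testing.assert_allclose(subtract_background(x, 0.0).samples, x.samples)

    def test_negative_background_rejected(self):
        with pytest.raises(ValidationError):
            subtract_background(_trace([1.0]), -0.1)


class TestMvcReference:
    def test_constant_trials_return_constant(self):
        trials = [_trace(np.full(600, 0.3)) for _ in range(4)]
        assert mvc_reference(trials) == pytest.approx(0.3)

    def test_mean_of_per_trial_maxima(self):
        trials = [_trace(np.full(600, v)) for v in (1.0, 2.0, 3.0, 4.0)]
        assert mvc_reference(trials) == pytest.approx(2.5)

    def test_single_trial_allowed(self):
        assert mvc_reference([_trace(np.full(600, 1.5))]) == pytest.approx(1.5)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            mvc_reference([])

    def test_smoothing_suppresses_isolated_spike(self):
        samples = np.full(1000, 0.2)
        samples[500] = 5.0  # single-sample artifact
        ref = mvc_reference([_trace(samples)], window_s=0.25)
        assert ref < 0.25  # spike contributes ~1/250th, not its full height


class TestNormalize:
    def test_reference_level_is_100_percent(self):
        out = normalize(_trace(np.full(10, 0.4)), background=0.0, reference=0.4)
        np.testing.assert_allclose(out.series, 100.0)

    def test_background_level_is_zero_percent(self):
        out = normalize(_trace(np.full(10, 0.1)), background=0.1, reference=0.4)
        np.testing.assert_allclose(out.series, 0.0)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValidationError):
            normalize(_trace([0.1]), 0.0, 0.0)

    def test_synthetic_envelope_recovered(self, small_config):
        cfg = dataclasses.replace(small_config, background_noise_level=0.0)
        trace = generate_emg_channel(
            np.full(200_000, 5.0), cfg, np.random.default_rng(4)
        )
        out = normalize(trace, background=0.0, reference=cfg.mvc_volts)
        assert np.mean(out.series) == pytest.approx(5.0, rel=0.03)

    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, scale):
        # Scaling the raw trace and the MVC reference together leaves %MVC unchanged.
        samples = np.array([0.0, 0.1, 0.25, 0.5])
        base = normalize(_trace(samples), 0.0, 0.5).series
        scaled = normalize(_trace(samples * scale), 0.0, 0.5 * scale).series
        np.testing.assert_allclose(scaled, base, rtol=1e-9)


class TestCycles:
    def _events(self, times):
        return EventSet(EventKind.FOOT_STRIKES, times)

    def test_21_strikes_give_20_cycles(self):
        windows = segment_cycles(self._events(np.arange(21) * 700))
        assert len(windows) == 20

    def test_windows_are_half_open_strike_pairs(self):
        windows = segment_cycles(self._events([0, 1000, 2000]))
        assert windows == [(0, 1000), (1000, 2000)]

    def test_25_strikes_capped_at_20(self):
        windows = segment_cycles(self._events(np.arange(25) * 700))
        assert len(windows) == 20
        assert windows[0] == (0, 700)

    def test_single_strike_rejected(self):
        with pytest.raises(ValidationError):
            segment_cycles(self._events([100]))


class TestIntegration:
    def _activation(self, series, fs=2000.0):
        return normalize(_trace(np.asarray(series) / 100.0, fs=fs), 0.0, 1.0)

    def test_constant_rectangle(self):
        act = self._activation(np.full(1401, 10.0))
        assert integrate_cycle(act, (0, 1400)).value == pytest.approx(7.0)

    def test_zero_series(self):
        act = self._activation(np.zeros(100))
        assert integrate_cycle(act, (0, 99)).value == 0.0

    def test_triangular_envelope(self):
        n = 2001  # 1 s at 2 kHz, peak 10 at the midpoint
        tri = 10.0 * (1 - np.abs(np.linspace(-1, 1, n)))
        act = self._activation(tri)
        assert integrate_cycle(act, (0, 2000)).value == pytest.approx(5.0, rel=1e-6)

    def test_empty_window_rejected(self):
        act = self._activation(np.ones(10))
        with pytest.raises(ValidationError):
            integrate_cycle(act, (5, 5))


class TestBinProfile:
    def test_even_division_pairs(self):
        series = np.arange(200.0)
        out = bin_profile(series, (0, 200), 100)
        np.testing.assert_allclose(out, np.arange(100) * 2 + 0.5)

    def test_constant_preserved(self):
        out = bin_profile(np.full(350, 4.2), (0, 350), 100)
        np.testing.assert_allclose(out, 4.2)

    def test_remainder_goes_to_earliest_bins(self):
        # 205 samples over 100 bins: first 5 bins span 3 samples, rest 2.
        series = np.arange(205.0)
        out = bin_profile(series, (0, 205), 100)
        np.testing.assert_allclose(out[:5], [1.0, 4.0, 7.0, 10.0, 13.0])
        np.testing.assert_allclose(out[5:7], [15.5, 17.5])

    def test_window_shorter_than_bins_rejected(self):
        with pytest.raises(ValidationError):
            bin_profile(np.ones(50), (0, 50), 100)

    @given(n=st.integers(min_value=100, max_value=400))
    @settings(max_examples=25, deadline=None)
    def test_bin_mean_conserves_window_mean_on_even_division(self, n):
        rng = np.random.default_rng(n)
        series = rng.normal(size=n * 4)
        out = bin_profile(series, (0, 4 * n), n)
        assert np.mean(out) == pytest.approx(np.mean(series), rel=1e-9, abs=1e-12)


class TestEnsemble:
    def test_identical_profiles_zero_ci_width(self):
        prof = np.arange(10.0)
        out = ensemble_average([prof, prof.copy(), prof.copy()])
        np.testing.assert_allclose(out.ci_high - out.ci_low, 0.0, atol=1e-12)

    def test_two_subject_t_interval(self):
        out = ensemble_average([np.array([0.0]), np.array([2.0])])
        assert out.bin_means[0] == pytest.approx(1.0)
        # t(df=1, 0.975) = 12.706; SE = sd/sqrt(2) = 1
        assert out.ci_high[0] == pytest.approx(1.0 + 12.706, rel=1e-3)
        assert out.ci_low[0] == pytest.approx(1.0 - 12.706, rel=1e-3)

    def test_single_unit_flags_undefined_ci(self):
        out = ensemble_average([np.array([1.0, 2.0])])
        assert not out.ci_defined
        np.testing.assert_allclose(out.bin_means, [1.0, 2.0])


class TestActivationRatio:
    def test_identical_conditions_give_unity(self):
        assert activation_ratio([3.0, 4.0], [3.0, 4.0]) == pytest.approx(1.0)

    def test_known_multiplier(self):
        assert activation_ratio([2.0, 4.0], [1.0, 2.0]) == pytest.approx(2.0)

    def test_nonpositive_control_excluded(self):
        assert activation_ratio([1.0], [0.0]) is None
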