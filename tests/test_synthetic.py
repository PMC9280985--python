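"""Generator contracts: AM linearity, determinism, stride/jump construction."""

import dataclasses

import numpy as np
import pytest

from neckcore.signal_model import Condition, ValidationError
from neckcore.synthetic_data import (
    SyntheticConfig,
    _subject_traits,
    build_study,
    generate_emg_channel,
    generate_jump_trial,
    generate_mvc_and_rest,
    generate_running_trial,
    generate_study,
)


class TestEmgChannel:
    def test_zero_envelope_zero_noise_is_silent(self, small_config, rng):
        cfg = dataclasses.replace(small_config, background_noise_level=0.0)
        trace = generate_emg_channel(np.zeros(1000), cfg, rng)
        assert np.all(trace.samples == 0)

    def test_negative_envelope_rejected(self, small_config, rng):
        with pytest.raises(ValidationError):
            generate_emg_channel(np.array([1.0, -0.1]), small_config, rng)

    def test_rectified_mean_linear_in_envelope(self, small_config):
        # Doubling a constant envelope doubles the mean rectified amplitude
        # (Monte-Carlo check on 10^6 samples, noise off).
        cfg = dataclasses.replace(small_config, background_noise_level=0.0)
        n = 1_000_000
        a = generate_emg_channel(np.full(n, 5.0), cfg, np.random.default_rng(1))
        b = generate_emg_channel(np.full(n, 10.0), cfg, np.random.default_rng(2))
        ratio = np.mean(np.abs(b.samples)) / np.mean(np.abs(a.samples))
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_rectified_mean_calibrated_to_envelope(self, small_config):
        cfg = dataclasses.replace(small_config, background_noise_level=0.0)
        trace = generate_emg_channel(np.full(500_000, 5.0), cfg, np.random.default_rng(3))
        expected = 5.0 / 100.0 * cfg.mvc_volts
        assert np.mean(np.abs(trace.samples)) == pytest.approx(expected, rel=0.02)

    def test_same_seed_identical_traces(self, small_config):
        env = np.full(2000, 3.0)
        a = generate_emg_channel(env, small_config, np.random.default_rng(9))
        b = generate_emg_channel(env, small_config, np.random.default_rng(9))
        np.testing.assert_array_equal(a.samples, b.samples)


class TestRunningTrial:
    def test_strikes_evenly_spaced_at_stride_frequency(self, small_config, rng):
        cfg = dataclasses.replace(small_config, stride_frequency_sd=0.0)
        trial, truth = generate_running_trial("S01", Condition.CONTROL, cfg, rng)
        strikes = truth.event_indices
        assert strikes.size == cfg.n_cycles + 1
        spacing = np.diff(strikes) / cfg.fs
        np.testing.assert_allclose(spacing, 1.0 / cfg.stride_frequency, atol=2 / cfg.fs)

    def test_flight_phase_vertical_near_zero(self, small_config, rng):
        trial, truth = generate_running_trial("S01", Condition.CONTROL, small_config, rng)
        vert = trial.channels["accel_neck_vert"].samples
        fs, f = small_config.fs, small_config.stride_frequency
        duty = small_config.duty_factor
        for a, b in zip(truth.event_indices[:-1], truth.event_indices[1:]):
            lo = a + int(1.1 * duty * (b - a))
            flight = vert[lo:b]
            # flight reads the sensor offset only (plus noise)
            assert abs(np.mean(flight) - small_config.accel.vertical_flight_offset) < 0.05

    def test_condition_multiplier_scales_envelope_integral_exactly(self, small_config, rng):
        cfg = dataclasses.replace(small_config, stride_frequency_sd=0.0)
        traits = _subject_traits(cfg, 0, rng)
        _, ctrl = generate_running_trial("S01", Condition.CONTROL, cfg, rng, traits=traits)
        _, pull = generate_running_trial("S01", Condition.FORWARD_PULL, cfg, rng, traits=traits)
        expected = cfg.multiplier(Condition.FORWARD_PULL, "sternohyoid")
        assert pull.multipliers["sternohyoid"] == pytest.approx(expected)
        ratio = pull.envelopes["sternohyoid"].sum() / ctrl.envelopes["sternohyoid"].sum()
        assert ratio == pytest.approx(expected, rel=1e-9)

    def test_unknown_condition_rejected(self, small_config, rng):
        with pytest.raises(ValidationError):
            generate_running_trial("S01", Condition.JUMP_CONTROL, small_config, rng)


class TestJumpTrial:
    def test_takeoff_velocity_is_impulse_over_mass(self, small_config, rng):
        trial, truth = generate_jump_trial("S01", Condition.JUMP_CONTROL, small_config, rng)
        assert truth.takeoff_velocity == pytest.approx(truth.net_impulse / trial.body_mass)

    def test_net_impulse_fidelity_below_half_percent(self, small_config, rng):
        cfg = dataclasses.replace(
            small_config, jump=dataclasses.replace(small_config.jump, force_noise_rms=0.0)
        )
        trial, truth = generate_jump_trial("S01", Condition.JUMP_CONTROL, cfg, rng)
        force = trial.channels["force_z"].samples
        takeoff = truth.event_indices[1]
        measured = np.trapezoid(force[: takeoff + 1] - truth.effective_weight, dx=1 / cfg.fs)
        assert abs(measured - truth.net_impulse) / truth.net_impulse < 0.005

    def test_added_gravity_raises_standing_plateau(self, small_config, rng):
        trial, truth = generate_jump_trial("S01", Condition.JUMP_GRAVITY, small_config, rng)
        plateau = np.mean(trial.channels["force_z"].samples[: int(0.5 * small_config.fs)])
        expected = trial.body_mass * 9.81 + small_config.jump.applied_gravity_force
        assert plateau == pytest.approx(expected, rel=0.01)
        assert truth.effective_weight == pytest.approx(expected)

    def test_zero_impulse_degenerate_jump_is_flat(self, small_config, rng):
        jc = dataclasses.replace(
            small_config.jump,
            impulse_by_condition={"jump_control": 0.0},
            force_noise_rms=0.0,
        )
        cfg = dataclasses.replace(small_config, jump=jc)
        trial, truth = generate_jump_trial("S01", Condition.JUMP_CONTROL, cfg, rng)
        force = trial.channels["force_z"].samples
        np.testing.assert_allclose(force, trial.body_mass * 9.81, rtol=1e-9)
        assert truth.net_impulse == 0.0 and truth.takeoff_velocity == 0.0

    def test_unreachable_impulse_rejected(self, small_config, rng):
        jc = dataclasses.replace(small_config.jump, impulse_by_condition={"jump_control": 5000.0})
        cfg = dataclasses.replace(small_config, jump=jc)
        with pytest.raises(ValidationError, match="unreachable"):
            generate_jump_trial("S01", Condition.JUMP_CONTROL, cfg, rng)


class TestMvcAndRest:
    def test_nine_trials_per_subject(self, small_config, rng):
        trials = generate_mvc_and_rest("S01", small_config, rng)
        conditions = [t.condition for t, _ in trials]
        assert len(trials) == 9
        assert conditions.count(Condition.MVC_FLEXION) == 4
        assert conditions.count(Condition.MVC_EXTENSION) == 4
        assert conditions.count(Condition.REST) == 1

    def test_rest_trial_reads_background_level(self, small_config, rng):
        trials = generate_mvc_and_rest("S01", small_config, rng)
        rest = [t for t, _ in trials if t.condition is Condition.REST][0]
        level = np.mean(np.abs(rest.channels["sternohyoid"].samples))
        assert level == pytest.approx(small_config.background_noise_level, rel=0.1)

    def test_mvc_amplitude_at_reference_level(self, small_config, rng):
        cfg = dataclasses.replace(small_config, background_noise_level=0.0, mvc_trial_duration=2.0)
        trials = generate_mvc_and_rest("S01", cfg, rng)
        amplitudes = [
            np.mean(np.abs(t.channels["sternohyoid"].samples))
            for t, _ in trials
            if t.condition is Condition.MVC_FLEXION
        ]
        np.testing.assert_allclose(amplitudes, cfg.mvc_volts, rtol=0.05)


class TestStudyAssembly:
    def test_fixed_seed_regenerates_identical_files(self, tmp_path, small_config):
        cfg = dataclasses.replace(small_config, n_subjects=1)
        generate_study(cfg, tmp_path / "a", conditions=[Condition.CONTROL])
        generate_study(cfg, tmp_path / "b", conditions=[Condition.CONTROL])
        fa = (tmp_path / "a" / "S01" / "control_00.tsv").read_bytes()
        fb = (tmp_path / "b" / "S01" / "control_00.tsv").read_bytes()
        assert fa == fb

    def test_availability_mask_reduces_muscle_n(self, small_config):
        cfg = dataclasses.replace(small_config, unavailable={"masseter": ("S02",)})
        study = build_study(cfg, conditions=[Condition.CONTROL])
        assert study.available_subjects("masseter") == ["S01"]
        assert study.available_subjects("sternohyoid") == ["S01", "S02"]

    def test_trial_counts_per_subject(self, small_config):
        study = build_study(
            small_config, conditions=[Condition.CONTROL, Condition.JUMP_CONTROL]
        )
        assert len(study.get("S01", Condition.CONTROL)) == 1
        assert len(study.get("S01", Condition.JUMP_CONTROL)) == small_config.jump.jumps_per_condition
        assert len(study.get("S01", Condition.MVC_FLEXION)) == 4
        assert len(study.get("S01", Condition.REST)) == 1

    def test_submax_jump_count_is_twenty(self, small_config):
        study = build_study(small_config, conditions=[Condition.JUMP_SUBMAX])
        submax = study.get("S01", Condition.JUMP_SUBMAX)
        assert len(submax) == 20  # 5 effort levels x 4 jumps
        assert sorted({t.effort_pct for t in submax}) == [10.0, 25.0, 50.0, 75.0, 90.0]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(duty_factor=1.5)
        with pytest.raises(ValidationError):
            SyntheticConfig(multipliers={Condition.CONTROL: {"sternohyoid": 0.0}})
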