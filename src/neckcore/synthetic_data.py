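"""Synthetic multi-subject study generator with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be scored against a known answer:

* **EMG** — a zero-mean Gaussian carrier band-pass filtered to the surface
  EMG band (default 20–400 Hz, zero phase) and normalized to unit mean
  rectified amplitude, multiplied by a nonnegative activation envelope in
  %MVC.  The expected mean rectified amplitude therefore *is* the envelope
  (times the subject's MVC voltage scale), which makes integrated-EMG
  estimates linear in the envelope.  Broadband instrumentation noise of
  configurable rectified-mean amplitude is added on top.
* **Running kinematics** — stride-periodic proper-acceleration traces:
  each stride cycle holds one stance pulse followed by a flight segment in
  which vertical proper acceleration is ≈ 0, plus a foot-mounted channel
  with one sharp transient per foot strike.  (A real running stride
  contains two single-support steps; the single stance pulse is a
  deliberate simplification that still exercises flight-phase baselining,
  strike detection and per-step statistics.)
* **Jump kinetics** — countermovement force–time curves built from an
  unweighting dip, a propulsion peak, a release ramp to takeoff, a
  ballistic flight and a landing spike, constructed so that the net
  impulse above effective weight over the push-off equals a configured
  target exactly (analytically, before sampling).
* **Effect multipliers** — each (muscle, condition) pair scales the whole
  activation envelope by a configured multiplier; the shipped defaults
  mirror the group-mean activation ratios of the study the pipeline
  reproduces, so recovery runs are one command.

Everything is deterministic under a fixed seed (per-trial random streams
are spawned from one ``SeedSequence``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import signal as sps

from .signal_model import (
    ChannelTrace,
    Condition,
    FORCE_CHANNEL,
    JUMP_CONDITIONS,
    MUSCLES,
    PULL_CONDITIONS,
    RUNNING_CONDITIONS,
    Study,
    StudyManifest,
    Trial,
    Units,
    ValidationError,
    write_trial,
)

G = 9.81  # m s^-2


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BurstSpec:
    """One stride-phase-locked activation burst (wrapped Gaussian in phase)."""

    phase: float  # cycle fraction in [0, 1)
    width: float  # SD as a cycle fraction
    amplitude: float  # %MVC at the bump peak

    def __post_init__(self) -> None:
        if not 0 <= self.phase < 1:
            raise ValidationError("burst phase must lie in [0, 1)")
        if self.width <= 0 or self.amplitude < 0:
            raise ValidationError("burst width must be > 0 and amplitude >= 0")


@dataclass(frozen=True)
class MuscleEnvelope:
    """Running-trial activation envelope: tonic level plus phasic bursts."""

    tonic: float  # %MVC
    bursts: tuple[BurstSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.tonic < 0:
            raise ValidationError("tonic level must be nonnegative")


def _biphasic(tonic: float, p1: float, p2: float, amp1: float, amp2: float,
              width: float = 0.06) -> MuscleEnvelope:
    return MuscleEnvelope(
        tonic=tonic,
        bursts=(BurstSpec(p1, width, amp1), BurstSpec(p2, width, amp2)),
    )


def default_running_envelopes() -> dict[str, MuscleEnvelope]:
    """Low tonic activity plus low biphasic stride-locked bursts.

    Phases follow the qualitative description of cervical activity during
    running: ventral strap muscles burst around mid-support, the levator
    scapulae around foot contact, and the dorsal muscles just before foot
    contact, with activity overall in the 0.4–6 %MVC range.
    """
    return {
        "sternohyoid": _biphasic(0.8, 0.15, 0.65, 2.5, 2.0),
        "sternocleidomastoid": _biphasic(0.8, 0.20, 0.70, 2.0, 3.0),
        "masseter": MuscleEnvelope(tonic=0.6, bursts=(BurstSpec(0.2, 0.08, 1.0),)),
        "levator_scapulae": _biphasic(1.0, 0.02, 0.52, 3.0, 2.0),
        "upper_trapezius": _biphasic(1.2, 0.95, 0.45, 3.0, 3.0),
        "splenius_capitis": _biphasic(1.0, 0.93, 0.43, 3.5, 3.0),
        "semispinalis_right": _biphasic(1.0, 0.92, 0.42, 3.0, 3.0),
        "semispinalis_left": _biphasic(1.0, 0.42, 0.92, 3.0, 3.0),
    }


@dataclass(frozen=True)
class JumpEnvelope:
    """Jump activation envelope locked to jump phases (%MVC amplitudes)."""

    tonic: float = 1.0
    push_amplitude: float = 20.0
    push_width_s: float = 0.12
    flight_level: float = 3.0
    landing_amplitude: float = 15.0
    landing_width_s: float = 0.06


def default_jump_envelopes() -> dict[str, JumpEnvelope]:
    env = {}
    for m in MUSCLES:
        dorsal = m not in ("sternohyoid", "sternocleidomastoid", "masseter")
        env[m] = JumpEnvelope(
            tonic=1.0,
            push_amplitude=25.0 if dorsal else 12.0,
            flight_level=2.0 if dorsal else 6.0,
            landing_amplitude=18.0 if dorsal else 8.0,
        )
    return env


def default_multipliers() -> dict[Condition, dict[str, float]]:
    """Per-muscle, per-condition envelope multipliers.

    Defaults mirror the group-mean integrated-activity ratios reported for
    each force manipulation (running: added head mass, forward pull,
    rearward pull, pulls with added head mass — all relative to the
    unmanipulated control; jumps: integrated-area ratios), so that a
    default synthetic study reproduces those group means by construction.
    """
    tables = {
        Condition.HEAD_MASS: (1.24, 1.30, 0.71, 1.21, 1.26, 1.10, 1.07, 1.10),
        Condition.FORWARD_PULL: (3.63, 2.74, 1.53, 1.78, 1.23, 1.50, 1.33, 1.29),
        Condition.FORWARD_PULL_MASS: (3.74, 2.65, 0.84, 1.96, 2.03, 2.08, 1.37, 1.68),
        Condition.REARWARD_PULL: (2.27, 1.72, 1.17, 2.15, 1.96, 2.01, 1.82, 1.80),
        Condition.REARWARD_PULL_MASS: (2.32, 1.59, 0.77, 2.18, 1.91, 2.13, 1.84, 1.87),
        Condition.JUMP_GRAVITY: (0.92, 1.06, 1.15, 1.10, 0.99, 0.93, 0.94, 1.01),
        Condition.JUMP_MASS: (1.00, 1.06, 0.86, 1.13, 0.95, 1.10, 0.98, 1.00),
    }
    out: dict[Condition, dict[str, float]] = {
        cond: dict(zip(MUSCLES, vals)) for cond, vals in tables.items()
    }
    for cond in (Condition.CONTROL, Condition.JUMP_CONTROL, Condition.JUMP_SUBMAX):
        out[cond] = {m: 1.0 for m in MUSCLES}
    return out


@dataclass(frozen=True)
class AccelConfig:
    """Proper-acceleration trace parameters (neck + foot channels)."""

    vertical_stance_peak: float = 38.5  # m/s^2; cycle mean ~= 9.3 at duty 0.38
    vertical_flight_offset: float = 0.3  # sensor bias the pipeline must remove
    fore_aft_stance_amp: float = 9.6  # control braking/propulsion amplitude
    pull_stance_peak: float = 25.2  # unidirectional stance peak under pulls
    fore_aft_offset: float = 0.5  # fore-aft sensor bias
    foot_spike_amplitude: float = 50.0  # m/s^2
    foot_spike_width_s: float = 0.005
    noise_rms: float = 0.15  # m/s^2 additive sensor noise


@dataclass(frozen=True)
class JumpConfig:
    """Countermovement-jump force-curve parameters."""

    quiet_duration: float = 1.0  # s of quiet standing before movement
    unweighting_duration: float = 0.35
    unweighting_fraction: float = 0.5  # dip amplitude as a fraction of weight
    push_duration: float = 0.40
    release_duration: float = 0.04  # weight -> 0 ramp ending at takeoff
    landing_duration: float = 0.12
    landing_peak_bw: float = 3.0
    tail_duration: float = 0.25
    max_peak_bw: float = 6.0  # reachability guard on the propulsion peak
    target_net_impulse: float = 203.7  # N s, maximal-effort control jumps
    impulse_by_condition: dict[str, float] = field(
        default_factory=lambda: {
            Condition.JUMP_CONTROL.value: 203.7,
            Condition.JUMP_GRAVITY.value: 159.5,
            Condition.JUMP_MASS.value: 210.5,
        }
    )
    applied_gravity_force: float = 270.0  # N downward in added-gravity jumps
    force_noise_rms: float = 2.0  # N plate noise
    effort_levels: tuple[float, ...] = (10.0, 25.0, 50.0, 75.0, 90.0)
    jumps_per_condition: int = 4
    emg_effort_b: float = 0.012  # integrated EMG ~ exp(b * net impulse)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-level configuration; defaults encode the study conditions."""

    n_subjects: int = 16
    seed: int = 0
    fs: float = 2000.0
    stride_frequency: float = 1.4  # Hz
    stride_frequency_sd: float = 0.05  # between-subject spread
    n_cycles: int = 20
    duty_factor: float = 0.38  # stance fraction of the cycle
    body_mass_mean: float = 73.7  # kg
    body_mass_sd: float = 7.3
    head_added_mass: float = 4.5  # kg (2.25 kg per side)
    applied_pull_force: float = 175.0  # N, within the 150-200 N acceptance band
    emg_carrier_band: tuple[float, float] = (20.0, 400.0)
    mvc_volts: float = 5.0e-4  # rectified-mean EMG at 100 %MVC
    background_noise_level: float = 1.0e-6  # rectified-mean noise, volts
    mvc_trial_duration: float = 2.0  # s
    rest_trial_duration: float = 2.5  # s
    n_mvc_trials: int = 4
    subject_multiplier_sd: float = 0.0  # between-subject spread of true effect
    envelopes: dict[str, MuscleEnvelope] = field(default_factory=default_running_envelopes)
    jump_envelopes: dict[str, JumpEnvelope] = field(default_factory=default_jump_envelopes)
    multipliers: dict[Condition, dict[str, float]] = field(default_factory=default_multipliers)
    accel: AccelConfig = field(default_factory=AccelConfig)
    jump: JumpConfig = field(default_factory=JumpConfig)
    unavailable: dict[str, tuple[str, ...]] = field(default_factory=dict)
    # ^ muscle -> subject ids whose electrode is discarded

    def __post_init__(self) -> None:
        if not 0 < self.duty_factor < 1:
            raise ValidationError("duty factor must lie in (0, 1)")
        if self.n_subjects < 1 or self.fs <= 0 or self.n_cycles < 1:
            raise ValidationError("n_subjects, fs and n_cycles must be positive")
        if self.background_noise_level < 0:
            raise ValidationError("background noise level must be nonnegative")
        for cond, per_muscle in self.multipliers.items():
            for m, v in per_muscle.items():
                if not v > 0:
                    raise ValidationError(f"multiplier for {m}/{cond} must be > 0")

    def subject_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    def multiplier(self, condition: Condition, muscle: str) -> float:
        return self.multipliers.get(condition, {}).get(muscle, 1.0)


@dataclass
class GroundTruth:
    """Per-trial generator truth, sufficient to score pipeline outputs."""

    condition: Condition
    event_indices: np.ndarray | None = None  # foot strikes or (onset, takeoff, landing)
    multipliers: dict[str, float] = field(default_factory=dict)
    envelopes: dict[str, np.ndarray] | None = None  # %MVC series per muscle
    vertical_offset: float | None = None
    fore_aft_offset: float | None = None
    net_impulse: float | None = None
    takeoff_velocity: float | None = None
    effective_weight: float | None = None


# ---------------------------------------------------------------------------
# EMG carrier
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _carrier_sos(band: tuple[float, float], fs: float):
    low, high = band
    nyq = fs / 2
    high = min(high, 0.95 * nyq)
    return sps.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")


def generate_emg_channel(
    envelope: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
    *,
    noise_level: float | None = None,
) -> ChannelTrace:
    """Amplitude-modulate a band-limited stochastic carrier by ``envelope``.

    ``envelope`` is in %MVC; the output is in volts with expected mean
    rectified amplitude ``envelope / 100 * config.mvc_volts`` plus the
    additive broadband background noise (rectified mean
    ``config.background_noise_level`` volts by default).
    """
    envelope = np.asarray(envelope, dtype=float)
    if np.any(envelope < 0):
        raise ValidationError("EMG envelope must be nonnegative")
    n = envelope.size
    if np.all(envelope == 0):
        carrier = np.zeros(n)
    else:
        white = rng.standard_normal(n)
        carrier = sps.sosfiltfilt(_carrier_sos(config.emg_carrier_band, config.fs), white)
        carrier /= np.mean(np.abs(carrier))  # unit mean rectified amplitude
    signal = envelope / 100.0 * config.mvc_volts * carrier
    b = config.background_noise_level if noise_level is None else noise_level
    if b > 0:
        # E|N(0, s)| = s * sqrt(2/pi); choose s so the rectified mean is b.
        sigma = b * math.sqrt(math.pi / 2.0)
        signal = signal + sigma * rng.standard_normal(n)
    return ChannelTrace(samples=signal, fs=config.fs, units=Units.VOLTS)


def _wrapped_gaussian(u: np.ndarray, phase: float, width: float) -> np.ndarray:
    out = np.zeros_like(u)
    for k in (-1.0, 0.0, 1.0):
        out += np.exp(-0.5 * ((u - phase - k) / width) ** 2)
    return out


def running_envelope(
    spec: MuscleEnvelope, phase: np.ndarray, multiplier: float = 1.0
) -> np.ndarray:
    """Evaluate a stride-locked envelope (%MVC) at cycle phases in [0, 1)."""
    env = np.full_like(phase, spec.tonic, dtype=float)
    for burst in spec.bursts:
        env += burst.amplitude * _wrapped_gaussian(phase, burst.phase, burst.width)
    return multiplier * env


# ---------------------------------------------------------------------------
# Running trials
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _SubjectTraits:
    body_mass: float
    stride_frequency: float
    multiplier_jitter: dict[str, float]


def _subject_traits(config: SyntheticConfig, subject_index: int, rng: np.random.Generator) -> _SubjectTraits:
    mass = float(np.clip(rng.normal(config.body_mass_mean, config.body_mass_sd), 45.0, 120.0))
    freq = float(np.clip(rng.normal(config.stride_frequency, config.stride_frequency_sd), 0.8, 2.5))
    jitter = {}
    for m in MUSCLES:
        if config.subject_multiplier_sd > 0:
            jitter[m] = float(
                np.clip(rng.normal(1.0, config.subject_multiplier_sd), 0.05, None)
            )
        else:
            jitter[m] = 1.0
    return _SubjectTraits(body_mass=mass, stride_frequency=freq, multiplier_jitter=jitter)


def generate_running_trial(
    subject: str,
    condition: Condition | str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    *,
    traits: _SubjectTraits | None = None,
) -> tuple[Trial, GroundTruth]:
    """One treadmill trial: 8 EMG channels + neck/foot accelerometry.

    Foot strikes are evenly spaced at the subject's stride frequency;
    ``config.n_cycles`` complete cycles are contained in the trace.
    """
    condition = Condition(condition)
    if condition not in RUNNING_CONDITIONS:
        raise ValidationError(f"{condition.value!r} is not a running condition")
    if traits is None:
        traits = _subject_traits(config, 0, rng)
    fs = config.fs
    f_stride = traits.stride_frequency
    period = 1.0 / f_stride
    t0 = 0.05
    duration = t0 + (config.n_cycles) * period + 0.1
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    strike_times = t0 + np.arange(config.n_cycles + 1) * period
    strike_idx = np.round(strike_times * fs).astype(int)

    phase = ((t - t0) * f_stride) % 1.0
    stance = phase < config.duty_factor
    u_stance = phase / config.duty_factor  # stance-normalized phase

    acc = config.accel
    noise = lambda: acc.noise_rms * rng.standard_normal(n)

    vert = np.where(stance, acc.vertical_stance_peak * np.sin(np.pi * np.clip(u_stance, 0, 1)), 0.0)
    vert = vert + acc.vertical_flight_offset + noise()

    if condition in (Condition.FORWARD_PULL, Condition.FORWARD_PULL_MASS):
        fa_pattern = np.where(stance, -acc.pull_stance_peak * np.sin(np.pi * u_stance), 0.0)
    elif condition in (Condition.REARWARD_PULL, Condition.REARWARD_PULL_MASS):
        fa_pattern = np.where(stance, acc.pull_stance_peak * np.sin(np.pi * u_stance), 0.0)
    else:
        fa_pattern = np.where(stance, -acc.fore_aft_stance_amp * np.sin(2 * np.pi * u_stance), 0.0)
    fa = fa_pattern + acc.fore_aft_offset + noise()

    ml = noise()

    foot = np.zeros(n)
    sig = acc.foot_spike_width_s
    for st in strike_times:
        lo = max(0, int((st - 4 * sig) * fs))
        hi = min(n, int((st + 4 * sig) * fs) + 1)
        foot[lo:hi] += acc.foot_spike_amplitude * np.exp(
            -0.5 * ((t[lo:hi] - st) / sig) ** 2
        )
    foot += noise()

    channels: dict[str, ChannelTrace] = {}
    multipliers: dict[str, float] = {}
    envelopes: dict[str, np.ndarray] = {}
    for muscle in MUSCLES:
        mult = config.multiplier(condition, muscle) * traits.multiplier_jitter[muscle]
        env = running_envelope(config.envelopes[muscle], phase, mult)
        channels[muscle] = generate_emg_channel(env, config, rng)
        multipliers[muscle] = mult
        envelopes[muscle] = env

    channels["accel_neck_vert"] = ChannelTrace(vert, fs, Units.ACCELERATION)
    channels["accel_neck_fa"] = ChannelTrace(fa, fs, Units.ACCELERATION)
    channels["accel_neck_ml"] = ChannelTrace(ml, fs, Units.ACCELERATION)
    channels["accel_foot"] = ChannelTrace(foot, fs, Units.ACCELERATION)

    head_mass = (
        config.head_added_mass
        if condition in (Condition.HEAD_MASS, Condition.FORWARD_PULL_MASS, Condition.REARWARD_PULL_MASS)
        else 0.0
    )
    applied = config.applied_pull_force if condition in PULL_CONDITIONS else 0.0
    trial = Trial(
        subject_id=subject,
        condition=condition,
        channels=channels,
        body_mass=traits.body_mass,
        head_added_mass=head_mass,
        applied_force=applied,
    )
    truth = GroundTruth(
        condition=condition,
        event_indices=strike_idx,
        multipliers=multipliers,
        envelopes=envelopes,
        vertical_offset=acc.vertical_flight_offset,
        fore_aft_offset=acc.fore_aft_offset,
    )
    return trial, truth


# ---------------------------------------------------------------------------
# Jump trials
# ---------------------------------------------------------------------------


def _jump_force_profile(
    config: SyntheticConfig,
    weight: float,
    target_impulse: float,
) -> tuple[np.ndarray, dict[str, float]]:
    """Build a countermovement force curve with exact net impulse.

    Phases: quiet standing at the effective weight W, unweighting half-sine
    dip (amplitude A1 = f*W over T1), propulsion half-sine above W
    (amplitude A2 over T2), release ramp W·cos over T3 ending at zero force
    (takeoff), ballistic flight of duration 2·v/g, landing half-sine spike,
    then quiet standing.  A2 is solved from the impulse balance

        J = (2/π)A2·T2 − (2/π)A1·T1 − (1 − 2/π)·W·T3.
    """
    jc = config.jump
    fs = config.fs
    if target_impulse < 0:
        raise ValidationError("target net impulse must be nonnegative")
    if target_impulse == 0:
        # degenerate "jump": quiet standing only — flat trace, no flight
        n = int(round((jc.quiet_duration + jc.tail_duration) * fs))
        return np.full(n, weight), {
            "a2": 0.0,
            "movement_start": n - 1,
            "takeoff_index": n - 1,
            "onset_time_in_dip": 0.0,
        }
    a1 = jc.unweighting_fraction * weight
    t1, t2, t3 = jc.unweighting_duration, jc.push_duration, jc.release_duration
    a2 = (target_impulse + (2 / math.pi) * a1 * t1 + (1 - 2 / math.pi) * weight * t3) * math.pi / (
        2 * t2
    )
    if a2 + weight > jc.max_peak_bw * weight:
        raise ValidationError(
            f"target impulse {target_impulse} N s unreachable for configured durations"
        )
    mass_equiv = weight / G  # only used for flight duration bookkeeping
    v_takeoff = None  # filled by caller (depends on true body mass)

    def seg(duration: float) -> np.ndarray:
        return np.arange(int(round(duration * fs))) / fs

    quiet = np.full(int(round(jc.quiet_duration * fs)), weight)
    s1 = seg(t1)
    dip = weight - a1 * np.sin(np.pi * s1 / t1)
    s2 = seg(t2)
    push = weight + a2 * np.sin(np.pi * s2 / t2)
    s3 = seg(t3)
    release = weight * np.cos(np.pi * s3 / (2 * t3))
    info = {
        "a2": a2,
        "movement_start": quiet.size,
        "takeoff_index": quiet.size + s1.size + s2.size + s3.size,
        # onset as detected: first 10% drop below the weight during the dip
        "onset_time_in_dip": t1 / math.pi * math.asin(min(1.0, 0.1 * weight / a1)),
    }
    return np.concatenate([quiet, dip, push, release]), info


def _jump_envelope_series(
    spec: JumpEnvelope,
    t: np.ndarray,
    t_push_peak: float,
    t_takeoff: float,
    t_landing: float,
    multiplier: float,
) -> np.ndarray:
    env = np.full_like(t, spec.tonic)
    env += spec.push_amplitude * np.exp(-0.5 * ((t - t_push_peak) / spec.push_width_s) ** 2)
    in_flight = (t >= t_takeoff) & (t < t_landing)
    env[in_flight] += spec.flight_level
    env += spec.landing_amplitude * np.exp(-0.5 * ((t - t_landing) / spec.landing_width_s) ** 2)
    return multiplier * env


def generate_jump_trial(
    subject: str,
    condition: Condition | str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    *,
    traits: _SubjectTraits | None = None,
    effort_pct: float | None = None,
) -> tuple[Trial, GroundTruth]:
    """One force-plate countermovement jump with phase-locked EMG.

    ``jump_gravity`` adds a constant downward force to the effective
    weight; ``jump_submax`` scales the target impulse by ``effort_pct`` and
    the EMG envelope by exp(b·ΔJ) so integrated EMG rises exponentially
    with jump impulse.
    """
    condition = Condition(condition)
    if condition not in JUMP_CONDITIONS:
        raise ValidationError(f"{condition.value!r} is not a jump condition")
    if condition is Condition.JUMP_SUBMAX and effort_pct is None:
        raise ValidationError("submax jumps require effort_pct")
    if traits is None:
        traits = _subject_traits(config, 0, rng)
    jc = config.jump
    fs = config.fs
    mass = traits.body_mass + (config.head_added_mass if condition is Condition.JUMP_MASS else 0.0)
    applied = jc.applied_gravity_force if condition is Condition.JUMP_GRAVITY else 0.0
    weight = mass * G + applied

    if condition is Condition.JUMP_SUBMAX:
        target_impulse = (effort_pct / 100.0) * jc.impulse_by_condition[Condition.JUMP_CONTROL.value]
    else:
        target_impulse = jc.impulse_by_condition.get(condition.value, jc.target_net_impulse)

    prof, info = _jump_force_profile(config, weight, target_impulse)
    if target_impulse == 0:
        force = prof + (
            jc.force_noise_rms * rng.standard_normal(prof.size) if jc.force_noise_rms > 0 else 0.0
        )
        channels = {
            m: generate_emg_channel(
                np.full(prof.size, config.jump_envelopes[m].tonic), config, rng
            )
            for m in MUSCLES
        }
        channels[FORCE_CHANNEL] = ChannelTrace(force, fs, Units.NEWTONS)
        trial = Trial(
            subject,
            condition,
            channels,
            traits.body_mass,
            head_added_mass=config.head_added_mass if condition is Condition.JUMP_MASS else 0.0,
            applied_force=applied,
            effort_pct=effort_pct,
        )
        truth = GroundTruth(
            condition=condition,
            net_impulse=0.0,
            takeoff_velocity=0.0,
            effective_weight=weight,
        )
        return trial, truth
    v_takeoff = target_impulse / mass
    t_flight = 2 * v_takeoff / G
    n_flight = int(round(t_flight * fs))
    flight = np.zeros(n_flight)
    s_land = np.arange(int(round(jc.landing_duration * fs))) / fs
    landing_spike = jc.landing_peak_bw * weight * np.sin(np.pi * s_land / jc.landing_duration)
    tail = np.full(int(round(jc.tail_duration * fs)), weight)
    force = np.concatenate([prof, flight, landing_spike, tail])
    n = force.size
    t = np.arange(n) / fs
    if jc.force_noise_rms > 0:
        force = force + jc.force_noise_rms * rng.standard_normal(n)

    movement_start = info["movement_start"]
    takeoff_idx = info["takeoff_index"]
    landing_idx = takeoff_idx + n_flight
    onset_idx = movement_start + int(round(info["onset_time_in_dip"] * fs))

    t_push_peak = (movement_start / fs) + jc.unweighting_duration + jc.push_duration / 2

    channels: dict[str, ChannelTrace] = {}
    multipliers: dict[str, float] = {}
    envelopes: dict[str, np.ndarray] = {}
    effort_scale = 1.0
    if condition is Condition.JUMP_SUBMAX:
        j_max = jc.impulse_by_condition[Condition.JUMP_CONTROL.value]
        effort_scale = math.exp(jc.emg_effort_b * (target_impulse - j_max))
    for muscle in MUSCLES:
        mult = config.multiplier(condition, muscle) * traits.multiplier_jitter[muscle]
        env = _jump_envelope_series(
            config.jump_envelopes[muscle],
            t,
            t_push_peak,
            takeoff_idx / fs,
            landing_idx / fs,
            mult * effort_scale,
        )
        channels[muscle] = generate_emg_channel(env, config, rng)
        multipliers[muscle] = mult
        envelopes[muscle] = env

    channels[FORCE_CHANNEL] = ChannelTrace(force, fs, Units.NEWTONS)
    trial = Trial(
        subject_id=subject,
        condition=condition,
        channels=channels,
        body_mass=traits.body_mass,
        head_added_mass=config.head_added_mass if condition is Condition.JUMP_MASS else 0.0,
        applied_force=applied,
        effort_pct=effort_pct,
    )
    truth = GroundTruth(
        condition=condition,
        event_indices=np.array([onset_idx, takeoff_idx, landing_idx]),
        multipliers=multipliers,
        envelopes=envelopes,
        net_impulse=target_impulse,
        takeoff_velocity=v_takeoff,
        effective_weight=weight,
    )
    return trial, truth


# ---------------------------------------------------------------------------
# MVC / rest
# ---------------------------------------------------------------------------


def generate_mvc_and_rest(
    subject: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    *,
    traits: _SubjectTraits | None = None,
) -> list[tuple[Trial, GroundTruth]]:
    """N MVC trials per direction (envelope at 100 %MVC) plus one rest trial.

    With the default N = 4 this yields 4 flexion + 4 extension + 1 rest =
    9 trials per subject.  The rest trial is background noise only.
    """
    if traits is None:
        traits = _subject_traits(config, 0, rng)
    out: list[tuple[Trial, GroundTruth]] = []
    n_mvc = int(round(config.mvc_trial_duration * config.fs))
    n_rest = int(round(config.rest_trial_duration * config.fs))
    for direction in (Condition.MVC_FLEXION, Condition.MVC_EXTENSION):
        for _ in range(config.n_mvc_trials):
            channels = {
                m: generate_emg_channel(np.full(n_mvc, 100.0), config, rng) for m in MUSCLES
            }
            trial = Trial(subject, direction, channels, traits.body_mass)
            out.append((trial, GroundTruth(condition=direction)))
    rest_channels = {
        m: generate_emg_channel(np.zeros(n_rest), config, rng) for m in MUSCLES
    }
    out.append(
        (
            Trial(subject, Condition.REST, rest_channels, traits.body_mass),
            GroundTruth(condition=Condition.REST),
        )
    )
    return out


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------

_DEFAULT_STUDY_CONDITIONS: tuple[Condition, ...] = (
    Condition.CONTROL,
    Condition.HEAD_MASS,
    Condition.FORWARD_PULL,
    Condition.REARWARD_PULL,
    Condition.FORWARD_PULL_MASS,
    Condition.REARWARD_PULL_MASS,
    Condition.JUMP_CONTROL,
    Condition.JUMP_GRAVITY,
    Condition.JUMP_MASS,
    Condition.JUMP_SUBMAX,
)


def _spawn_rngs(config: SyntheticConfig, n: int) -> list[np.random.Generator]:
    seqs = np.random.SeedSequence(config.seed).spawn(n)
    return [np.random.default_rng(s) for s in seqs]


def iter_study_trials(
    config: SyntheticConfig,
    conditions: Sequence[Condition | str] | None = None,
) -> Iterator[tuple[str, Condition, int, Trial, GroundTruth]]:
    """Yield (subject, condition, repetition, trial, truth) deterministically.

    MVC and rest trials are always included.  ``conditions`` restricts the
    experimental conditions generated (useful when only one comparison is
    being scored); by default all running and jump conditions are emitted.
    """
    wanted = (
        {Condition(c) for c in conditions} if conditions is not None else set(_DEFAULT_STUDY_CONDITIONS)
    )
    subjects = config.subject_ids()
    subject_rngs = _spawn_rngs(config, config.n_subjects)
    for s_idx, subject in enumerate(subjects):
        rng = subject_rngs[s_idx]
        traits = _subject_traits(config, s_idx, rng)
        for trial, truth in generate_mvc_and_rest(subject, config, rng, traits=traits):
            yield subject, trial.condition, 0, trial, truth
        for cond in _DEFAULT_STUDY_CONDITIONS:
            if cond not in wanted:
                continue
            if cond in RUNNING_CONDITIONS:
                trial, truth = generate_running_trial(subject, cond, config, rng, traits=traits)
                yield subject, cond, 0, trial, truth
            elif cond is Condition.JUMP_SUBMAX:
                rep = 0
                for effort in config.jump.effort_levels:
                    for _ in range(config.jump.jumps_per_condition):
                        trial, truth = generate_jump_trial(
                            subject, cond, config, rng, traits=traits, effort_pct=effort
                        )
                        yield subject, cond, rep, trial, truth
                        rep += 1
            else:
                for rep in range(config.jump.jumps_per_condition):
                    trial, truth = generate_jump_trial(subject, cond, config, rng, traits=traits)
                    yield subject, cond, rep, trial, truth


def build_study(
    config: SyntheticConfig,
    conditions: Sequence[Condition | str] | None = None,
) -> Study:
    """Generate an in-memory :class:`Study` (with ground truth attached)."""
    trials: dict[str, dict[Condition, list[Trial]]] = {}
    truth: dict[str, dict[Condition, list[GroundTruth]]] = {}
    for subject, cond, _rep, trial, gt in iter_study_trials(config, conditions):
        trials.setdefault(subject, {}).setdefault(cond, []).append(trial)
        truth.setdefault(subject, {}).setdefault(cond, []).append(gt)
    availability = {
        muscle: [s for s in config.subject_ids() if s not in set(bad)]
        for muscle, bad in config.unavailable.items()
    }
    return Study(
        subjects=config.subject_ids(),
        trials=trials,
        availability=availability,
        truth=truth,
    )


def generate_study(
    config: SyntheticConfig,
    out_dir: str | Path,
    conditions: Sequence[Condition | str] | None = None,
) -> StudyManifest:
    """Write a full study tree of trial bundles plus ground-truth JSON.

    Layout: ``<out>/<subject>/<condition>_<rep>.tsv`` (+ sidecars), a
    ``manifest.yaml`` at the root and ground truth under ``<out>/truth/``.
    Byte-identical under a fixed seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "truth").mkdir(exist_ok=True)
    manifest_trials: dict[str, dict[str, list[str]]] = {}
    truth_payload: dict[str, dict[str, list[dict]]] = {}
    for subject, cond, rep, trial, gt in iter_study_trials(config, conditions):
        sub_dir = out_dir / subject
        sub_dir.mkdir(exist_ok=True)
        stem = f"{cond.value}_{rep:02d}"
        if trial.effort_pct is not None:
            stem = f"{cond.value}_{int(trial.effort_pct):02d}pct_{rep:02d}"
        rel = f"{subject}/{stem}.tsv"
        write_trial(trial, out_dir / rel)
        manifest_trials.setdefault(subject, {}).setdefault(cond.value, []).append(rel)
        entry = {
            "condition": cond.value,
            "repetition": rep,
            "multipliers": gt.multipliers,
            "event_indices": None if gt.event_indices is None else gt.event_indices.tolist(),
            "net_impulse": gt.net_impulse,
            "takeoff_velocity": gt.takeoff_velocity,
            "effective_weight": gt.effective_weight,
            "vertical_offset": gt.vertical_offset,
            "fore_aft_offset": gt.fore_aft_offset,
        }
        truth_payload.setdefault(subject, {}).setdefault(cond.value, []).append(entry)
    availability = {
        muscle: [s for s in config.subject_ids() if s not in set(bad)]
        for muscle, bad in config.unavailable.items()
    }
    manifest = StudyManifest(
        subjects=config.subject_ids(), trials=manifest_trials, availability=availability
    )
    manifest.save(out_dir / "manifest.yaml")
    (out_dir / "truth" / "ground_truth.json").write_text(json.dumps(truth_payload, indent=1))
    return manifest
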