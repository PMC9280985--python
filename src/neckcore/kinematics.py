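"""Accelerometer processing for running trials.

Smoothing (10-ms centered rolling mean), two-point gravity calibration,
foot-strike detection from the foot-mounted channel, flight-phase
baselining of the vertical axis, per-mode zero-offset estimation for the
fore-aft axis, per-step peak/mean statistics, and the optional cosine
tilt correction for trunk lean.

Conventions: traces hold proper acceleration (≈ 0 in flight, ≈ g when
standing).  Steps are strike-to-strike windows; "first/second half" is a
temporal midpoint split of that window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_model import (
    Calibration,
    ChannelTrace,
    DetectionError,
    EventKind,
    EventSet,
    ValidationError,
)

G = 9.81


@dataclass
class StepAcceleration:
    """Per-step acceleration summary (m·s⁻²) for vertical and fore-aft axes."""

    step_index: int
    peak_positive_vertical: float
    peak_negative_vertical: float
    mean_vertical: float
    mean_vertical_first_half: float
    mean_vertical_second_half: float
    peak_positive_fore_aft: float
    peak_negative_fore_aft: float
    mean_fore_aft: float
    mean_fore_aft_first_half: float
    mean_fore_aft_second_half: float


@dataclass(frozen=True)
class TiltCorrection:
    """Cosine correction for accelerometer tilt due to trunk lean."""

    lean_angle: float  # degrees
    factor: float  # cos(lean), in (0, 1]

    def correct(self, measured: np.ndarray | float) -> np.ndarray | float:
        return measured / self.factor


class OffsetMode(str, Enum):
    """Zero-acceleration baseline definition for the fore-aft axis.

    ``cycle_mean``: mean over an integral number of cycles (control /
    added-head-mass trials, where braking and propulsion cancel).
    ``step_peaks``: mean of per-step maxima (forward pull — the applied
    force removes all forward acceleration, so the peaks mark zero).
    ``step_minima``: mean of per-step minima (rearward pull, symmetric).
    """

    CYCLE_MEAN = "cycle_mean"
    STEP_PEAKS = "step_peaks"
    STEP_MINIMA = "step_minima"


def rolling_mean(trace: ChannelTrace, window_ms: float = 10.0) -> ChannelTrace:
    """Centered rolling mean over ``window_ms`` (odd sample count; 21 at
    2000 Hz), edges handled by shrinking the window."""
    if trace.n < 1:
        raise ValidationError("empty trace")
    window = int(round(window_ms * trace.fs / 1000.0))
    if window < 1:
        raise ValidationError("smoothing window shorter than one sample")
    if window % 2 == 0:
        window += 1
    smoothed = (
        pd.Series(trace.samples).rolling(window=window, center=True, min_periods=1).mean()
    )
    return trace.with_samples(smoothed.to_numpy())


def calibrate_gravity(
    static_up: ChannelTrace, static_down: ChannelTrace, g: float = G
) -> Calibration:
    """Two-point gravity calibration from static recordings with the axis
    vertical in opposite orientations.

    gain = 2g / (mean_up − mean_down) in m·s⁻²/V; the offset voltage is the
    midpoint, so physical = gain · (v − midpoint).
    """
    mean_up = float(np.mean(static_up.samples))
    mean_down = float(np.mean(static_down.samples))
    if mean_up <= mean_down:
        raise ValidationError("static recordings do not bracket gravity (orientation?)")
    gain = 2 * g / (mean_up - mean_down)
    midpoint = (mean_up + mean_down) / 2
    return Calibration(gain=gain, offset=-gain * midpoint)


def detect_foot_strikes(
    foot_trace: ChannelTrace,
    stride_freq_hint: float,
    k_mad: float = 6.0,
) -> EventSet:
    """One event per stride: local maxima of the foot-accelerometer trace
    exceeding median + k·MAD (default k = 6), with a refractory period of
    half the hinted stride period.

    The MAD threshold makes detection invariant to amplitude scaling.
    """
    if stride_freq_hint <= 0:
        raise ValidationError("stride frequency hint must be positive")
    x = foot_trace.samples
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0:
        raise DetectionError("foot trace has no variability; no transients to detect")
    height = med + k_mad * mad
    distance = max(1, int(round(0.5 / stride_freq_hint * foot_trace.fs)))
    peaks, _ = sps.find_peaks(x, height=height, distance=distance)
    if peaks.size == 0:
        raise DetectionError("no foot-strike transients found")
    return EventSet(kind=EventKind.FOOT_STRIKES, times=peaks, n_samples=foot_trace.n)


def vertical_baseline_flight(vert_trace: ChannelTrace, events: EventSet) -> float:
    """Vertical zero offset: mean over strides of the per-stride minimum.

    The minima fall in the flight phase, where proper acceleration is
    zero, so their mean estimates the sensor offset.  Expects the smoothed
    trace (single-sample noise minima would otherwise dominate).
    """
    windows = list(zip(events.times[:-1], events.times[1:]))
    if len(windows) < 1 or events.times.size < 2:
        raise ValidationError("need at least two strikes (one stride) for baselining")
    minima = [float(np.min(vert_trace.samples[a:b])) for a, b in windows]
    return float(np.mean(minima))


def horizontal_offset(
    fa_trace: ChannelTrace, events: EventSet, mode: OffsetMode | str
) -> float:
    """Fore-aft zero offset under the given baseline definition.

    See :class:`OffsetMode`.  ``cycle_mean`` averages over the integral
    number of cycles spanned by the events; the step modes average
    per-step extrema.
    """
    mode = OffsetMode(mode)
    if events.times.size < 2:
        raise ValidationError("need at least one complete cycle")
    a0, a1 = int(events.times[0]), int(events.times[-1])
    if mode is OffsetMode.CYCLE_MEAN:
        return float(np.mean(fa_trace.samples[a0:a1]))
    windows = list(zip(events.times[:-1], events.times[1:]))
    if mode is OffsetMode.STEP_PEAKS:
        vals = [float(np.max(fa_trace.samples[a:b])) for a, b in windows]
    else:
        vals = [float(np.min(fa_trace.samples[a:b])) for a, b in windows]
    return float(np.mean(vals))


def offset_mode_for_condition(condition: str) -> OffsetMode:
    if "forward_pull" in condition:
        return OffsetMode.STEP_PEAKS
    if "rearward_pull" in condition:
        return OffsetMode.STEP_MINIMA
    return OffsetMode.CYCLE_MEAN


def step_stats(
    vert_corrected: ChannelTrace,
    fa_corrected: ChannelTrace,
    events: EventSet,
) -> list[StepAcceleration]:
    """Per-step peaks and means of baselined vertical and fore-aft traces.

    Each step is one strike-to-strike window; half-step means split the
    window at its temporal midpoint.
    """
    if events.times.size < 2:
        raise ValidationError("need at least one step")
    out = []
    for i, (a, b) in enumerate(zip(events.times[:-1], events.times[1:])):
        mid = (a + b) // 2
        v = vert_corrected.samples[a:b]
        f = fa_corrected.samples[a:b]
        out.append(
            StepAcceleration(
                step_index=i,
                peak_positive_vertical=float(np.max(v)),
                peak_negative_vertical=float(np.min(v)),
                mean_vertical=float(np.mean(v)),
                mean_vertical_first_half=float(np.mean(vert_corrected.samples[a:mid])),
                mean_vertical_second_half=float(np.mean(vert_corrected.samples[mid:b])),
                peak_positive_fore_aft=float(np.max(f)),
                peak_negative_fore_aft=float(np.min(f)),
                mean_fore_aft=float(np.mean(f)),
                mean_fore_aft_first_half=float(np.mean(fa_corrected.samples[a:mid])),
                mean_fore_aft_second_half=float(np.mean(fa_corrected.samples[mid:b])),
            )
        )
    return out


def steps_to_frame(steps: list[StepAcceleration]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in steps])


def tilt_correction(angle_deg: float) -> TiltCorrection:
    """Cosine tilt-correction factor for a lean angle in degrees.

    The accelerometer tilted by θ under-reads the horizontal axis by
    cos θ (e.g. ≤ 12 % at 28°); corrected = measured / cos θ.  Not applied
    by default — opt in per trial.
    """
    if abs(angle_deg) >= 90:
        raise ValidationError("lean angle must satisfy |angle| < 90 degrees")
    return TiltCorrection(lean_angle=angle_deg, factor=math.cos(math.radians(angle_deg)))
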