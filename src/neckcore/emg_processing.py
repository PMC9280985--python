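"""Rectification, background correction, MVC normalization, cycle-locked
integration and binned ensemble profiles for surface EMG.

The processing chain mirrors standard locomotor-EMG practice: rectify,
subtract the resting background (mean of the 500 smallest rectified
samples of a relaxed recording), normalize to the per-subject MVC
reference (mean over MVC trials of the maximum of a 250-ms moving average
of the rectified trace, expressed as 100 %MVC), segment into locomotor
cycles at right-foot strikes, integrate per cycle (%MVC·s), and
time-normalize each window into a fixed number of bins for ensemble
averaging with Student-t confidence intervals.

The hierarchy for ensemble statistics is cycles → subject mean →
across-subject mean ± 95 % CI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .signal_model import ChannelTrace, EventSet, Units, ValidationError

#: Number of samples averaged to estimate the resting background level.
BACKGROUND_N_POINTS = 500

#: Default smoothing window (s) applied before taking MVC trial maxima.
MVC_SMOOTHING_WINDOW_S = 0.25

#: Cap on locomotor cycles analysed per running trial.
MAX_CYCLES_PER_TRIAL = 20


@dataclass
class NormalizedActivation:
    """Background-corrected, MVC-normalized activation in %MVC over time."""

    series: np.ndarray
    fs: float
    muscle: str = ""
    background_level: float = 0.0  # volts
    mvc_reference: float = 1.0  # volts at 100 %MVC

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if not self.mvc_reference > 0:
            raise ValidationError("MVC reference must be positive")
        if np.any(self.series < 0):
            raise ValidationError("normalized activation must be nonnegative (clipped)")


@dataclass
class CycleIntegral:
    """Integrated activation over one locomotor cycle or jump window."""

    value: float  # %MVC·s
    cycle_index: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError("cycle integral must be nonnegative")


@dataclass
class EnsembleProfile:
    """Binned mean ± 95 % CI activation profile over a normalized cycle."""

    n_bins: int
    bin_means: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_units: int
    ci_defined: bool = True

    def __post_init__(self) -> None:
        for arr in (self.bin_means, self.ci_low, self.ci_high):
            if np.asarray(arr).size != self.n_bins:
                raise ValidationError("profile arrays must have length n_bins")
        if self.ci_defined and (
            np.any(self.ci_low > self.bin_means + 1e-12)
            or np.any(self.ci_high < self.bin_means - 1e-12)
        ):
            raise ValidationError("CI must bracket the mean")


def rectify(trace: ChannelTrace) -> ChannelTrace:
    """Full-wave rectification (pointwise absolute value)."""
    if trace.units is not Units.VOLTS:
        raise ValidationError("rectification applies to EMG (volt) channels")
    return trace.with_samples(np.abs(trace.samples))


def estimate_background(rest: ChannelTrace, n_points: int = BACKGROUND_N_POINTS) -> float:
    """Resting background level: mean of the ``n_points`` smallest rectified
    samples of a relaxed recording."""
    samples = np.abs(rest.samples)
    if samples.size < n_points:
        raise ValidationError(
            f"rest recording has {samples.size} samples; need >= {n_points}"
        )
    lowest = np.partition(samples, n_points - 1)[:n_points]
    return float(np.mean(lowest))


def subtract_background(trace: ChannelTrace, background: float) -> ChannelTrace:
    """Subtract the resting background from a rectified trace, clipping at
    zero (negative activation is physically meaningless)."""
    if background < 0:
        raise ValidationError("background level must be nonnegative")
    return trace.with_samples(np.maximum(trace.samples - background, 0.0))


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    # centered moving mean with shrinking edge windows
    import pandas as pd

    return (
        pd.Series(x).rolling(window=window, center=True, min_periods=1).mean().to_numpy()
    )


def mvc_reference(
    mvc_traces: list[ChannelTrace],
    background: float = 0.0,
    window_s: float = MVC_SMOOTHING_WINDOW_S,
) -> float:
    """MVC normalization reference (volts at 100 %MVC).

    Per trial, the maximum of a centered moving average (default 250 ms) of
    the rectified, background-corrected trace; the reference is the mean of
    the per-trial maxima across the available MVC trials.  Raw single-sample
    maxima of a stochastic interference signal are noise-dominated, hence
    the smoothing.
    """
    if not mvc_traces:
        raise ValidationError("at least one MVC trial is required")
    maxima = []
    for trace in mvc_traces:
        window = max(1, int(round(window_s * trace.fs)))
        corrected = subtract_background(rectify(trace), background)
        maxima.append(float(np.max(_moving_average(corrected.samples, window))))
    return float(np.mean(maxima))


def normalize(
    trace: ChannelTrace,
    background: float,
    reference: float,
    muscle: str = "",
) -> NormalizedActivation:
    """Express a raw EMG trace in %MVC: rectify, subtract background, scale
    by the MVC reference."""
    if not reference > 0:
        raise ValidationError("MVC reference must be positive")
    corrected = subtract_background(rectify(trace), background)
    return NormalizedActivation(
        series=100.0 * corrected.samples / reference,
        fs=trace.fs,
        muscle=muscle,
        background_level=background,
        mvc_reference=reference,
    )


def segment_cycles(
    events: EventSet, max_cycles: int = MAX_CYCLES_PER_TRIAL
) -> list[tuple[int, int]]:
    """Half-open strike-to-strike windows [strike_i, strike_{i+1}).

    A locomotor cycle begins and ends with touch-down of the right foot;
    at most ``max_cycles`` cycles are retained per trial.
    """
    if events.times.size < 2:
        raise ValidationError("need at least two foot strikes to form a cycle")
    windows = [
        (int(a), int(b)) for a, b in zip(events.times[:-1], events.times[1:])
    ]
    return windows[:max_cycles]


def integrate_cycle(
    activation: NormalizedActivation, window: tuple[int, int], cycle_index: int = 0
) -> CycleIntegral:
    """Trapezoidal integral of %MVC over the window duration (%MVC·s).

    The right window edge is included as integration endpoint (when in
    range) so a window of w samples integrates exactly w/fs seconds.
    """
    a, b = window
    if b <= a:
        raise ValidationError("empty integration window")
    if a < 0 or b > activation.series.size:
        raise ValidationError("integration window outside the series")
    stop = min(b + 1, activation.series.size)
    value = float(np.trapezoid(activation.series[a:stop], dx=1.0 / activation.fs))
    return CycleIntegral(value=value, cycle_index=cycle_index)


def bin_profile(series: np.ndarray, window: tuple[int, int], n_bins: int) -> np.ndarray:
    """Time-normalize a window into ``n_bins`` contiguous bin means.

    Bins have near-equal length; when the window length is not a multiple
    of ``n_bins`` the remainder is distributed one extra sample per bin to
    the earliest bins.
    """
    a, b = window
    series = np.asarray(series, dtype=float)
    n = b - a
    if n < n_bins:
        raise ValidationError(f"window of {n} samples cannot fill {n_bins} bins")
    if a < 0 or b > series.size:
        raise ValidationError("window outside the series")
    base, rem = divmod(n, n_bins)
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:rem] += 1
    edges = a + np.concatenate([[0], np.cumsum(sizes)])
    chunk = series[a:b]
    csum = np.concatenate([[0.0], np.cumsum(chunk)])
    starts = edges[:-1] - a
    stops = edges[1:] - a
    return (csum[stops] - csum[starts]) / sizes


def ensemble_average(profiles: list[np.ndarray], confidence: float = 0.95) -> EnsembleProfile:
    """Across-unit mean and Student-t confidence interval per bin.

    ``profiles`` are same-length binned series, one per unit (cycles when
    building a subject profile, subjects when building the group profile).
    With fewer than two units the mean is returned and the CI flagged
    undefined.
    """
    if not profiles:
        raise ValidationError("no profiles to average")
    mat = np.vstack(profiles)
    n_units, n_bins = mat.shape
    mean = mat.mean(axis=0)
    if n_units < 2:
        return EnsembleProfile(
            n_bins=n_bins,
            bin_means=mean,
            ci_low=mean.copy(),
            ci_high=mean.copy(),
            n_units=n_units,
            ci_defined=False,
        )
    se = mat.std(axis=0, ddof=1) / math.sqrt(n_units)
    tq = spstats.t.ppf(0.5 + confidence / 2.0, df=n_units - 1)
    return EnsembleProfile(
        n_bins=n_bins,
        bin_means=mean,
        ci_low=mean - tq * se,
        ci_high=mean + tq * se,
        n_units=n_units,
    )


def activation_ratio(
    manip_integrals: list[float] | np.ndarray,
    control_integrals: list[float] | np.ndarray,
) -> float | None:
    """Per-subject manipulation/control activation ratio.

    Ratio of the mean cycle integral under the manipulation to the mean
    under control, computed on identically processed trials of one subject
    and muscle.  Returns None (subject excluded) when the control mean is
    not positive.
    """
    manip = np.asarray(manip_integrals, dtype=float)
    control = np.asarray(control_integrals, dtype=float)
    if manip.size == 0 or control.size == 0:
        raise ValidationError("both conditions need at least one integral")
    control_mean = control.mean()
    if control_mean <= 0:
        return None
    return float(manip.mean() / control_mean)


def group_ratio_summary(ratios: list[float]) -> tuple[float, float, int]:
    """Group mean ± SD of per-subject ratios (ddof=1)."""
    arr = np.asarray([r for r in ratios if r is not None], dtype=float)
    if arr.size == 0:
        raise ValidationError("no usable subject ratios")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return float(arr.mean()), sd, int(arr.size)
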