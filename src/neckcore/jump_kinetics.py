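"""Force-plate countermovement-jump analysis.

Implements the impulse–momentum method: the center-of-mass acceleration
is a(t) = (F(t) − W_eff)/m, velocity is its running trapezoidal integral
from movement onset, the net impulse is ∫(F − W_eff) dt over the push-off
and equals m·v_takeoff, and jump height follows from v²/(2g).  W_eff is
the quiet-standing baseline, which already includes any constant applied
downward force (added-gravity trials), so adding such a force leaves a(t)
unchanged.

Phase detection: movement onset is the first sustained (default 50 ms)
drop of force below 90 % of effective weight — the "10 % of body weight"
EMG-window rule read as a 10 % *drop*, since force near 10 % of body
weight only occurs at takeoff; the literal reading is available via
``onset_mode="literal"``.  Takeoff is the first force sample below an
absolute 10 N; landing is the first subsequent rise to 10 % of effective
weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_model import (
    ChannelTrace,
    DetectionError,
    EventKind,
    EventSet,
    Trial,
    ValidationError,
)

G = 9.81


@dataclass
class JumpKinetics:
    """Impulse–momentum kinetics of one countermovement jump."""

    body_weight: float  # N, effective (incl. applied downward force)
    mass: float  # kg
    onset: int
    takeoff: int
    landing: int
    net_impulse: float  # N·s above effective weight over push-off
    takeoff_velocity: float  # m/s
    jump_height: float  # m, from v^2 / 2g
    jump_height_flight: float  # m, from g * t_flight^2 / 8
    applied_force: float = 0.0  # N
    com_acceleration: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def __post_init__(self) -> None:
        if not (self.onset < self.takeoff < self.landing):
            raise ValidationError("jump phases must satisfy onset < takeoff < landing")


def body_weight_baseline(
    force_trace: ChannelTrace,
    quiet_window_s: float = 1.0,
    sd_threshold_frac: float = 0.05,
) -> float:
    """Effective body weight from the quietest standing window.

    Searches the pre-movement segment (from the trace start until force
    first deviates by more than 30 % from the initial level) for the
    window of ``quiet_window_s`` with minimum rolling SD and returns its
    mean force.  Raises :class:`DetectionError` if no window is quiet
    enough (SD above ``sd_threshold_frac`` of the baseline everywhere).
    """
    f = force_trace.samples
    w = int(round(quiet_window_s * force_trace.fs))
    if w < 2 or f.size < w:
        raise ValidationError("trace shorter than the quiet window")
    guess = float(np.mean(f[:w]))
    dev = np.abs(f - guess) > 0.3 * abs(guess)
    end = int(np.argmax(dev)) if dev.any() else f.size
    if end < w:
        raise DetectionError("no quiet standing segment at the trace start")
    region = pd.Series(f[:end])
    sds = region.rolling(window=w).std().to_numpy()
    means = region.rolling(window=w).mean().to_numpy()
    idx = int(np.nanargmin(sds))
    baseline = float(means[idx])
    if sds[idx] > sd_threshold_frac * abs(baseline):
        raise DetectionError("standing segment too noisy for a baseline")
    return baseline


def detect_jump_phases(
    force_trace: ChannelTrace,
    effective_weight: float,
    onset_mode: str = "relative",
    onset_drop_frac: float = 0.10,
    sustain_s: float = 0.05,
    takeoff_threshold_n: float = 10.0,
    landing_frac: float = 0.10,
) -> EventSet:
    """Locate countermovement onset, takeoff and landing on a force trace.

    ``onset_mode="relative"`` (default): onset is the first sample where
    force stays below (1 − onset_drop_frac)·W_eff for ``sustain_s``.
    ``onset_mode="literal"``: first sustained drop below
    onset_drop_frac·W_eff (the literal protocol wording).
    """
    f = force_trace.samples
    fs = force_trace.fs
    if onset_mode == "relative":
        onset_threshold = (1.0 - onset_drop_frac) * effective_weight
    elif onset_mode == "literal":
        onset_threshold = onset_drop_frac * effective_weight
    else:
        raise ValidationError(f"unknown onset mode {onset_mode!r}")
    sustain = max(1, int(round(sustain_s * fs)))
    below = f < onset_threshold
    # first index from which `sustain` consecutive samples are below threshold
    run = np.convolve(below.astype(int), np.ones(sustain, dtype=int), mode="valid")
    hits = np.flatnonzero(run == sustain)
    if hits.size == 0:
        raise DetectionError("no countermovement onset found (flat trace?)")
    onset = int(hits[0])

    off = np.flatnonzero(f[onset:] < takeoff_threshold_n)
    if off.size == 0:
        raise DetectionError("no takeoff found: force never approaches zero")
    takeoff = onset + int(off[0])

    land = np.flatnonzero(f[takeoff:] >= landing_frac * effective_weight)
    if land.size == 0:
        raise DetectionError("no landing found after takeoff")
    landing = takeoff + int(land[0])
    return EventSet(
        kind=EventKind.JUMP_PHASES,
        times=np.array([onset, takeoff, landing]),
        n_samples=force_trace.n,
    )


def com_kinematics(
    force_trace: ChannelTrace,
    mass: float,
    effective_weight: float,
    phases: EventSet,
    applied_force: float = 0.0,
    g: float = G,
) -> JumpKinetics:
    """Impulse–momentum center-of-mass kinetics for one jump.

    a(t) = (F − W_eff)/m over the whole trace; v(t) integrates a from
    onset; the net impulse is the trapezoidal integral of (F − W_eff) over
    [onset, takeoff] and equals m·v_takeoff by construction.  Jump height
    is reported both from takeoff velocity (v²/2g) and from flight time
    (g·t_f²/8) as a cross-check.
    """
    if mass <= 0:
        raise ValidationError("mass must be positive")
    f = force_trace.samples
    fs = force_trace.fs
    onset, takeoff, landing = phases.onset, phases.takeoff, phases.landing
    accel = (f - effective_weight) / mass
    push = accel[onset : takeoff + 1]
    velocity = np.concatenate([[0.0], np.cumsum((push[1:] + push[:-1]) / 2.0) / fs])
    v_takeoff = float(velocity[-1])
    net_impulse = mass * v_takeoff  # trapezoid of (F - W) over the same window
    if v_takeoff < 0:
        raise DetectionError("negative takeoff velocity: phases mis-detected")
    t_flight = (landing - takeoff) / fs
    return JumpKinetics(
        body_weight=effective_weight,
        mass=mass,
        onset=onset,
        takeoff=takeoff,
        landing=landing,
        net_impulse=float(net_impulse),
        takeoff_velocity=v_takeoff,
        jump_height=v_takeoff**2 / (2 * g),
        jump_height_flight=g * t_flight**2 / 8.0,
        applied_force=applied_force,
        com_acceleration=accel,
    )


def analyze_jump_trial(trial: Trial, **phase_kwargs) -> JumpKinetics:
    """Convenience wrapper: baseline → phases → kinetics for one trial."""
    force = trial.channels["force_z"]
    weight = body_weight_baseline(force)
    phases = detect_jump_phases(force, weight, **phase_kwargs)
    mass = trial.body_mass + trial.head_added_mass
    return com_kinematics(force, mass, weight, phases, applied_force=trial.applied_force)


def impulse_change(
    control_impulses: list[float] | np.ndarray,
    manip_impulses: list[float] | np.ndarray,
) -> float:
    """Signed percent change of the group-mean net impulse,
    100·(mean_control − mean_manip)/mean_control.

    Positive values are reductions.  Callers report the magnitude
    separately where only the size of the change is of interest.
    """
    control = np.asarray(control_impulses, dtype=float)
    manip = np.asarray(manip_impulses, dtype=float)
    mc = control.mean()
    if mc <= 0:
        raise ValidationError("control mean impulse must be positive")
    return float(100.0 * (mc - manip.mean()) / mc)


def effort_series(trials: list[tuple[float, JumpKinetics]]) -> pd.DataFrame:
    """Tabulate graded-effort jumps: (nominal effort %, net impulse).

    One row per jump, keyed by the nominal effort label, for the
    downstream EMG–impulse regression.
    """
    if len({e for e, _ in trials}) < 2:
        raise ValidationError("need at least two effort levels")
    rows = [
        {"effort_pct": effort, "net_impulse": kin.net_impulse, "takeoff_velocity": kin.takeoff_velocity}
        for effort, kin in trials
    ]
    return pd.DataFrame(rows).sort_values(["effort_pct", "net_impulse"], ignore_index=True)
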