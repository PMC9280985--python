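"""Orchestration: simulate → process → summarize, with reproducible outputs.

``run_running_analysis`` executes, per subject: foot-strike detection on
the foot accelerometer, EMG normalization (rest-trial background, MVC
reference), cycle segmentation (20-cycle cap), per-cycle integration,
100-bin profiles, accelerometer step statistics, and across-subject ratio
tables with one-tailed signed-rank tests and Holm correction.  Pull-plus-
head-mass conditions are compared against the corresponding pull trials,
not control.

``run_jump_analysis`` executes, per jump: quiet-standing baseline, phase
detection, impulse–momentum kinetics, the onset→landing EMG window with
maximum/mean/integrated metrics, 200-bin profiles, metric ratio tables,
and the graded-effort exponential fit of integrated EMG versus net
impulse.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import emg_processing as emg
from . import jump_kinetics as jk
from . import kinematics as kin
from .signal_model import (
    Condition,
    DetectionError,
    MUSCLES,
    Study,
    Trial,
)
from .stats import fit_exponential, ratio_table

logger = logging.getLogger("neckcore")

#: MVC direction used as each muscle's normalization reference: the three
#: ventral (flexor) muscles use the flexion MVC, the rest the extension MVC.
DEFAULT_MVC_DIRECTION: dict[str, Condition] = {
    m: (
        Condition.MVC_FLEXION
        if m in ("sternohyoid", "sternocleidomastoid", "masseter")
        else Condition.MVC_EXTENSION
    )
    for m in MUSCLES
}

#: (manipulation, baseline, one-tailed direction) per running comparison.
#: Pull + head-mass trials are compared to the pull trials, not control.
RUNNING_COMPARISONS: tuple[tuple[Condition, Condition, str], ...] = (
    (Condition.HEAD_MASS, Condition.CONTROL, "greater"),
    (Condition.FORWARD_PULL, Condition.CONTROL, "greater"),
    (Condition.REARWARD_PULL, Condition.CONTROL, "greater"),
    (Condition.FORWARD_PULL_MASS, Condition.FORWARD_PULL, "greater"),
    (Condition.REARWARD_PULL_MASS, Condition.REARWARD_PULL, "greater"),
)

#: Jump comparisons: added gravity predicts a *decrease* under the postural
#: hypothesis, added head mass an increase; directions are explicit.
JUMP_COMPARISONS: tuple[tuple[Condition, Condition, str], ...] = (
    (Condition.JUMP_GRAVITY, Condition.JUMP_CONTROL, "less"),
    (Condition.JUMP_MASS, Condition.JUMP_CONTROL, "greater"),
)


@dataclass(frozen=True)
class RunConfig:
    """Processing parameters for a pipeline run."""

    n_bins_running: int = 100
    n_bins_jump: int = 200
    mvc_window_s: float = emg.MVC_SMOOTHING_WINDOW_S
    max_cycles: int = emg.MAX_CYCLES_PER_TRIAL
    smoothing_window_ms: float = 10.0
    strike_k_mad: float = 6.0
    stride_freq_hint: float = 1.4
    alpha: float = 0.05
    onset_mode: str = "relative"
    peak_window_s: float = 0.05  # smoothing before the per-jump EMG maximum
    seed: int | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ResultBundle:
    """Tables + profiles + provenance from one pipeline run."""

    tables: dict[str, pd.DataFrame]
    profiles: dict[str, emg.EnsembleProfile] = field(default_factory=dict)
    fits: dict[str, object] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, frame in self.tables.items():
            frame.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
        for name, profile in self.profiles.items():
            pd.DataFrame(
                {
                    "bin": np.arange(profile.n_bins),
                    "mean": profile.bin_means,
                    "ci_low": profile.ci_low,
                    "ci_high": profile.ci_high,
                }
            ).to_csv(out_dir / f"profile_{name}.tsv", sep="\t", index=False)
        if self.fits:
            rows = [
                {"muscle": m, "a": f.a, "b": f.b, "rss": f.rss, "n": f.n, "converged": f.converged}
                for m, f in self.fits.items()
            ]
            pd.DataFrame(rows).to_csv(out_dir / "exp_fits.tsv", sep="\t", index=False)
        (out_dir / "provenance.json").write_text(json.dumps(self.provenance, indent=1))


class ConfigurationError(ValueError):
    """The study lacks conditions a requested analysis needs."""


# ---------------------------------------------------------------------------
# Per-subject normalization context
# ---------------------------------------------------------------------------


@dataclass
class SubjectNormalization:
    backgrounds: dict[str, float]  # muscle -> volts
    references: dict[str, float]  # muscle -> volts at 100 %MVC


def subject_normalization(
    study: Study,
    subject: str,
    config: RunConfig,
    mvc_direction: dict[str, Condition] = DEFAULT_MVC_DIRECTION,
) -> SubjectNormalization:
    """Background and MVC reference per muscle from rest and MVC trials."""
    rest_trials = study.get(subject, Condition.REST)
    if not rest_trials:
        raise ConfigurationError(f"subject {subject} has no rest trial")
    rest = rest_trials[0]
    backgrounds: dict[str, float] = {}
    references: dict[str, float] = {}
    for muscle in MUSCLES:
        if muscle not in rest.channels:
            continue
        bg = emg.estimate_background(emg.rectify(rest.channels[muscle]))
        mvc_trials = study.get(subject, mvc_direction[muscle])
        traces = [t.channels[muscle] for t in mvc_trials if muscle in t.channels]
        if not traces:
            continue
        backgrounds[muscle] = bg
        references[muscle] = emg.mvc_reference(traces, bg, window_s=config.mvc_window_s)
    return SubjectNormalization(backgrounds=backgrounds, references=references)


# ---------------------------------------------------------------------------
# Running analysis
# ---------------------------------------------------------------------------


def _running_events(trial: Trial, config: RunConfig):
    foot = kin.rolling_mean(trial.channels["accel_foot"], config.smoothing_window_ms)
    return kin.detect_foot_strikes(foot, config.stride_freq_hint, config.strike_k_mad)


def running_cycle_integrals(
    study: Study, config: RunConfig | None = None
) -> pd.DataFrame:
    """Per-subject, per-muscle, per-condition mean cycle integrals (%MVC·s)."""
    from .signal_model import RUNNING_CONDITIONS

    config = config or RunConfig()
    rows = []
    for subject in study.subjects:
        norm = subject_normalization(study, subject, config)
        for condition in sorted(study.trials.get(subject, {}), key=lambda c: c.value):
            if condition not in RUNNING_CONDITIONS:
                continue
            for trial in study.get(subject, condition):
                events = _running_events(trial, config)
                windows = emg.segment_cycles(events, config.max_cycles)
                for muscle in MUSCLES:
                    if muscle not in trial.channels or muscle not in norm.references:
                        continue
                    if subject not in study.available_subjects(muscle):
                        continue
                    activation = emg.normalize(
                        trial.channels[muscle],
                        norm.backgrounds[muscle],
                        norm.references[muscle],
                        muscle,
                    )
                    integrals = [
                        emg.integrate_cycle(activation, w, i).value
                        for i, w in enumerate(windows)
                    ]
                    rows.append(
                        {
                            "subject": subject,
                            "muscle": muscle,
                            "condition": condition.value,
                            "mean_integral": float(np.mean(integrals)),
                            "n_cycles": len(integrals),
                        }
                    )
    return pd.DataFrame(rows)


def running_ratio_tables(
    integrals: pd.DataFrame,
    comparisons: tuple[tuple[Condition, Condition, str], ...] = RUNNING_COMPARISONS,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Ratio summary + Holm-corrected signed-rank tests per comparison."""
    tables = {}
    have = set(integrals["condition"].unique()) if len(integrals) else set()
    for manip, baseline, direction in comparisons:
        if manip.value not in have or baseline.value not in have:
            continue
        per_subject: dict[str, dict[str, tuple[float, float]]] = {}
        for muscle in MUSCLES:
            sub = integrals[integrals["muscle"] == muscle]
            base = sub[sub["condition"] == baseline.value].set_index("subject")["mean_integral"]
            man = sub[sub["condition"] == manip.value].set_index("subject")["mean_integral"]
            common = base.index.intersection(man.index)
            if len(common) == 0:
                continue
            per_subject[muscle] = {s: (float(base[s]), float(man[s])) for s in common}
        if per_subject:
            tables[f"{manip.value}_vs_{baseline.value}"] = ratio_table(
                per_subject, direction=direction, alpha=alpha
            )
    return tables


def running_profiles(
    study: Study, config: RunConfig | None = None
) -> dict[str, emg.EnsembleProfile]:
    """Group ensemble profiles (100 bins) per muscle × condition.

    Hierarchy: per-cycle binned profiles → subject mean profile →
    across-subject mean ± 95 % t CI.
    """
    config = config or RunConfig()
    by_key: dict[str, list[np.ndarray]] = {}
    for subject in study.subjects:
        norm = subject_normalization(study, subject, config)
        for condition in study.trials.get(subject, {}):
            from .signal_model import RUNNING_CONDITIONS

            if condition not in RUNNING_CONDITIONS:
                continue
            for trial in study.get(subject, condition):
                events = _running_events(trial, config)
                windows = emg.segment_cycles(events, config.max_cycles)
                for muscle in MUSCLES:
                    if muscle not in trial.channels or muscle not in norm.references:
                        continue
                    if subject not in study.available_subjects(muscle):
                        continue
                    activation = emg.normalize(
                        trial.channels[muscle],
                        norm.backgrounds[muscle],
                        norm.references[muscle],
                        muscle,
                    )
                    cycle_profiles = [
                        emg.bin_profile(activation.series, w, config.n_bins_running)
                        for w in windows
                    ]
                    subject_mean = np.vstack(cycle_profiles).mean(axis=0)
                    by_key.setdefault(f"{muscle}_{condition.value}", []).append(subject_mean)
    return {key: emg.ensemble_average(profiles) for key, profiles in by_key.items()}


def running_step_summary(study: Study, config: RunConfig | None = None) -> pd.DataFrame:
    """Condition-level means of per-step accelerations across subjects."""
    config = config or RunConfig()
    rows = []
    for subject in study.subjects:
        for condition in study.trials.get(subject, {}):
            from .signal_model import RUNNING_CONDITIONS

            if condition not in RUNNING_CONDITIONS:
                continue
            for trial in study.get(subject, condition):
                events = _running_events(trial, config)
                vert = kin.rolling_mean(trial.channels["accel_neck_vert"], config.smoothing_window_ms)
                fa = kin.rolling_mean(trial.channels["accel_neck_fa"], config.smoothing_window_ms)
                v_off = kin.vertical_baseline_flight(vert, events)
                f_off = kin.horizontal_offset(
                    fa, events, kin.offset_mode_for_condition(condition.value)
                )
                steps = kin.step_stats(
                    vert.with_samples(vert.samples - v_off),
                    fa.with_samples(fa.samples - f_off),
                    events,
                )
                frame = kin.steps_to_frame(steps)
                rows.append(
                    {
                        "subject": subject,
                        "condition": condition.value,
                        "mean_vertical": frame["mean_vertical"].mean(),
                        "mean_fore_aft": frame["mean_fore_aft"].mean(),
                        "mean_fore_aft_second_half": frame["mean_fore_aft_second_half"].mean(),
                        "peak_positive_vertical": frame["peak_positive_vertical"].mean(),
                        "peak_negative_fore_aft": frame["peak_negative_fore_aft"].mean(),
                        "n_steps": len(frame),
                    }
                )
    per_trial = pd.DataFrame(rows)
    if per_trial.empty:
        return per_trial
    return (
        per_trial.groupby("condition", as_index=False)
        .agg(
            mean_vertical=("mean_vertical", "mean"),
            sd_vertical=("mean_vertical", "std"),
            mean_fore_aft=("mean_fore_aft", "mean"),
            sd_fore_aft=("mean_fore_aft", "std"),
            mean_fore_aft_second_half=("mean_fore_aft_second_half", "mean"),
            n_subjects=("subject", "nunique"),
        )
    )


def run_running_analysis(study: Study, config: RunConfig | None = None) -> ResultBundle:
    """Full treadmill-running analysis: EMG ratios + stats, profiles, steps."""
    config = config or RunConfig()
    from .signal_model import RUNNING_CONDITIONS

    present = {c for c in study.conditions() if c in RUNNING_CONDITIONS}
    if not present:
        raise ConfigurationError("study contains no running conditions")
    integrals = running_cycle_integrals(study, config)
    tables: dict[str, pd.DataFrame] = {"cycle_integrals": integrals}
    tables.update(
        {
            f"ratios_{name}": tbl
            for name, tbl in running_ratio_tables(integrals, alpha=config.alpha).items()
        }
    )
    steps = running_step_summary(study, config)
    if not steps.empty:
        tables["step_summary"] = steps
    profiles = running_profiles(study, config)
    return ResultBundle(
        tables=tables,
        profiles=profiles,
        provenance={"analysis": "running", "config": config.to_dict(), "config_hash": config.digest()},
    )


# ---------------------------------------------------------------------------
# Jump analysis
# ---------------------------------------------------------------------------


def jump_trial_metrics(
    trial: Trial,
    norm: SubjectNormalization,
    config: RunConfig,
    availability: set[str] | None = None,
) -> tuple[jk.JumpKinetics, dict[str, dict[str, float]], dict[str, np.ndarray]]:
    """Kinetics plus per-muscle EMG metrics over the onset→landing window.

    Metrics per muscle: maximum voltage (max of a short moving average of
    the normalized rectified EMG — a raw single-sample maximum of a
    stochastic interference signal is noise-dominated, as for the MVC
    reference), mean voltage and integrated area (all in %MVC units), plus
    a 200-bin profile of the window.
    """
    force = trial.channels["force_z"]
    weight = jk.body_weight_baseline(force)
    phases = jk.detect_jump_phases(force, weight, onset_mode=config.onset_mode)
    mass = trial.body_mass + trial.head_added_mass
    kinetics = jk.com_kinematics(force, mass, weight, phases, applied_force=trial.applied_force)
    window = (phases.onset, phases.landing)
    metrics: dict[str, dict[str, float]] = {}
    profiles: dict[str, np.ndarray] = {}
    for muscle in MUSCLES:
        if muscle not in trial.channels or muscle not in norm.references:
            continue
        if availability is not None and muscle not in availability:
            continue
        activation = emg.normalize(
            trial.channels[muscle], norm.backgrounds[muscle], norm.references[muscle], muscle
        )
        seg = activation.series[window[0] : window[1]]
        peak_w = max(1, int(round(config.peak_window_s * trial.fs)))
        smoothed = pd.Series(seg).rolling(peak_w, center=True, min_periods=1).mean()
        metrics[muscle] = {
            "max": float(smoothed.max()),
            "mean": float(np.mean(seg)),
            "integral": emg.integrate_cycle(activation, window).value,
        }
        if window[1] - window[0] >= config.n_bins_jump:
            profiles[muscle] = emg.bin_profile(activation.series, window, config.n_bins_jump)
    return kinetics, metrics, profiles


def run_jump_analysis(study: Study, config: RunConfig | None = None) -> ResultBundle:
    """Full countermovement-jump analysis.

    Produces per-jump kinetics, per-subject condition means of the three
    EMG metrics, metric ratio tables with Holm-corrected one-tailed tests,
    group impulse summaries with percent changes, 200-bin group profiles,
    and — when graded-effort jumps are present — the exponential fit of
    integrated EMG versus net impulse per muscle.  Trials whose phases
    cannot be detected are skipped and logged, not fatal.
    """
    config = config or RunConfig()
    from .signal_model import JUMP_CONDITIONS

    present = {c for c in study.conditions() if c in JUMP_CONDITIONS}
    if not present:
        raise ConfigurationError("study contains no jump conditions")

    kinetic_rows = []
    metric_rows = []
    effort_rows = []
    profile_acc: dict[str, dict[str, list[np.ndarray]]] = {}
    for subject in study.subjects:
        norm = subject_normalization(study, subject, config)
        for condition in present:
            for rep, trial in enumerate(study.get(subject, condition)):
                try:
                    kinetics, metrics, profiles = jump_trial_metrics(
                        trial,
                        norm,
                        config,
                        availability={
                            m for m in MUSCLES if subject in study.available_subjects(m)
                        },
                    )
                except DetectionError as exc:
                    logger.warning(
                        "skipping %s/%s rep %d: %s", subject, condition.value, rep, exc
                    )
                    continue
                kinetic_rows.append(
                    {
                        "subject": subject,
                        "condition": condition.value,
                        "repetition": rep,
                        "effort_pct": trial.effort_pct,
                        "net_impulse": kinetics.net_impulse,
                        "takeoff_velocity": kinetics.takeoff_velocity,
                        "jump_height": kinetics.jump_height,
                        "jump_height_flight": kinetics.jump_height_flight,
                        "body_weight": kinetics.body_weight,
                    }
                )
                for muscle, vals in metrics.items():
                    metric_rows.append(
                        {
                            "subject": subject,
                            "condition": condition.value,
                            "repetition": rep,
                            "muscle": muscle,
                            **vals,
                        }
                    )
                    if condition is Condition.JUMP_SUBMAX:
                        effort_rows.append(
                            {
                                "subject": subject,
                                "muscle": muscle,
                                "effort_pct": trial.effort_pct,
                                "net_impulse": kinetics.net_impulse,
                                "integral": vals["integral"],
                            }
                        )
                for muscle, prof in profiles.items():
                    profile_acc.setdefault(f"{muscle}_{condition.value}", {}).setdefault(
                        subject, []
                    ).append(prof)

    kinetics_frame = pd.DataFrame(kinetic_rows)
    metrics_frame = pd.DataFrame(metric_rows)
    tables: dict[str, pd.DataFrame] = {"jump_kinetics": kinetics_frame, "jump_metrics": metrics_frame}

    # Per-subject condition means of each metric, then ratio tables.
    if not metrics_frame.empty:
        subject_means = (
            metrics_frame.groupby(["subject", "condition", "muscle"], as_index=False)[
                ["max", "mean", "integral"]
            ].mean()
        )
        tables["jump_subject_means"] = subject_means
        for manip, baseline, direction in JUMP_COMPARISONS:
            if manip not in present or baseline not in present:
                continue
            for metric in ("max", "mean", "integral"):
                per_subject: dict[str, dict[str, tuple[float, float]]] = {}
                for muscle in MUSCLES:
                    sub = subject_means[subject_means["muscle"] == muscle]
                    base = sub[sub["condition"] == baseline.value].set_index("subject")[metric]
                    man = sub[sub["condition"] == manip.value].set_index("subject")[metric]
                    common = base.index.intersection(man.index)
                    if len(common):
                        per_subject[muscle] = {
                            s: (float(base[s]), float(man[s])) for s in common
                        }
                if per_subject:
                    tables[f"ratios_{metric}_{manip.value}_vs_{baseline.value}"] = ratio_table(
                        per_subject, direction=direction, alpha=config.alpha
                    )

    # Group impulse summary + percent changes between conditions.
    if not kinetics_frame.empty:
        max_effort = kinetics_frame[kinetics_frame["condition"] != Condition.JUMP_SUBMAX.value]
        summary = (
            max_effort.groupby("condition", as_index=False)
            .agg(
                mean_impulse=("net_impulse", "mean"),
                sd_impulse=("net_impulse", "std"),
                mean_height=("jump_height", "mean"),
                n_jumps=("net_impulse", "size"),
            )
        )
        changes = []
        ctrl = max_effort[max_effort["condition"] == Condition.JUMP_CONTROL.value]["net_impulse"]
        if len(ctrl):
            for cond in (Condition.JUMP_GRAVITY, Condition.JUMP_MASS):
                vals = max_effort[max_effort["condition"] == cond.value]["net_impulse"]
                if len(vals):
                    signed = jk.impulse_change(ctrl.to_numpy(), vals.to_numpy())
                    changes.append(
                        {
                            "condition": cond.value,
                            "signed_percent_change": signed,
                            "magnitude_percent_change": abs(signed),
                        }
                    )
        tables["impulse_summary"] = summary
        if changes:
            tables["impulse_changes"] = pd.DataFrame(changes)

    # Group profiles: jumps -> subject mean -> across-subject ensemble.
    group_profiles: dict[str, emg.EnsembleProfile] = {}
    for key, by_subject in profile_acc.items():
        subject_means_p = [np.vstack(ps).mean(axis=0) for ps in by_subject.values()]
        group_profiles[key] = emg.ensemble_average(subject_means_p)

    # Graded-effort exponential fits per muscle.
    fits = {}
    if effort_rows:
        effort_frame = pd.DataFrame(effort_rows)
        tables["effort_series"] = effort_frame
        for muscle in effort_frame["muscle"].unique():
            sub = effort_frame[effort_frame["muscle"] == muscle]
            if len(sub) >= 3:
                fits[muscle] = fit_exponential(
                    sub["net_impulse"].to_numpy(), sub["integral"].to_numpy()
                )

    return ResultBundle(
        tables=tables,
        profiles=group_profiles,
        fits=fits,
        provenance={"analysis": "jump", "config": config.to_dict(), "config_hash": config.digest()},
    )
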