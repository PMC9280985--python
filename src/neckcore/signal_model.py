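"""Domain containers and file I/O for multi-channel locomotor trials.

A *trial* is one synchronously sampled recording: surface-EMG channels
(volts), accelerometer channels (m·s⁻² after calibration) and/or a
vertical ground-reaction-force channel (newtons), plus metadata (subject,
condition, body mass, any applied external force).  Trials are stored on
disk as a TSV numeric matrix (one column per channel, header row of
channel names) with a JSON sidecar ``<stem>.meta.json`` carrying sampling
rate, units and per-channel (gain, offset) calibration.  Calibration is
applied at read time, so everything downstream sees physical units.

Event indices are 0-based sample indices; time in seconds = index / fs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
import numpy as np
import pandas as pd
import yaml


class ValidationError(ValueError):
    """A domain invariant was violated."""


class FormatError(ValueError):
    """A file did not conform to the trial-bundle format."""


class DetectionError(RuntimeError):
    """An event/segment detector found nothing usable."""


class Units(str, Enum):
    VOLTS = "V"
    ACCELERATION = "m/s^2"
    NEWTONS = "N"


class Condition(str, Enum):
    """Experimental condition of a trial.

    Running conditions manipulate horizontal force at the pelvis and/or
    head mass; jump conditions manipulate effective gravity and head mass;
    MVC and rest trials provide the normalization reference and the noise
    floor.
    """

    CONTROL = "control"
    HEAD_MASS = "head_mass"
    FORWARD_PULL = "forward_pull"
    REARWARD_PULL = "rearward_pull"
    FORWARD_PULL_MASS = "forward_pull_mass"
    REARWARD_PULL_MASS = "rearward_pull_mass"
    JUMP_CONTROL = "jump_control"
    JUMP_GRAVITY = "jump_gravity"
    JUMP_MASS = "jump_mass"
    JUMP_SUBMAX = "jump_submax"
    MVC_FLEXION = "mvc_flexion"
    MVC_EXTENSION = "mvc_extension"
    REST = "rest"


RUNNING_CONDITIONS = frozenset(
    {
        Condition.CONTROL,
        Condition.HEAD_MASS,
        Condition.FORWARD_PULL,
        Condition.REARWARD_PULL,
        Condition.FORWARD_PULL_MASS,
        Condition.REARWARD_PULL_MASS,
    }
)
PULL_CONDITIONS = frozenset(
    {
        Condition.FORWARD_PULL,
        Condition.REARWARD_PULL,
        Condition.FORWARD_PULL_MASS,
        Condition.REARWARD_PULL_MASS,
    }
)
JUMP_CONDITIONS = frozenset(
    {Condition.JUMP_CONTROL, Condition.JUMP_GRAVITY, Condition.JUMP_MASS, Condition.JUMP_SUBMAX}
)

#: Muscles monitored by the study protocol (seven cervical + one jaw adductor).
MUSCLES = (
    "sternohyoid",
    "sternocleidomastoid",
    "masseter",
    "levator_scapulae",
    "upper_trapezius",
    "splenius_capitis",
    "semispinalis_right",
    "semispinalis_left",
)

#: Accelerometer channel names: neck 3-axis + foot (stride synchronization).
ACCEL_CHANNELS = ("accel_neck_vert", "accel_neck_fa", "accel_neck_ml", "accel_foot")

FORCE_CHANNEL = "force_z"
APPLIED_FORCE_CHANNEL = "applied_force"


@dataclass(frozen=True)
class Calibration:
    """Linear calibration: physical = gain * raw + offset."""

    gain: float = 1.0
    offset: float = 0.0

    def apply(self, raw: np.ndarray) -> np.ndarray:
        return self.gain * np.asarray(raw, dtype=float) + self.offset

    def invert(self, physical: np.ndarray) -> np.ndarray:
        return (np.asarray(physical, dtype=float) - self.offset) / self.gain


@dataclass
class ChannelTrace:
    """A uniformly sampled numeric series with units and calibration."""

    samples: np.ndarray
    fs: float
    units: Units = Units.VOLTS
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.units = Units(self.units)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError("channel samples must be a non-empty 1-D series")
        if not self.fs > 0:
            raise ValidationError(f"sampling frequency must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("channel samples must be finite")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray) -> "ChannelTrace":
        return replace(self, samples=np.asarray(samples, dtype=float))


def _expected_units(name: str) -> Units:
    if name == FORCE_CHANNEL or name == APPLIED_FORCE_CHANNEL:
        return Units.NEWTONS
    if name.startswith("accel"):
        return Units.ACCELERATION
    return Units.VOLTS


@dataclass
class Trial:
    """One recording: named channels sharing a sampling rate, plus metadata."""

    subject_id: str
    condition: Condition
    channels: dict[str, ChannelTrace]
    body_mass: float
    head_added_mass: float = 0.0
    applied_force: float = 0.0
    effort_pct: float | None = None

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        if not self.channels:
            raise ValidationError("trial must carry at least one channel")
        if not self.body_mass > 0:
            raise ValidationError("body mass must be positive")
        fs_values = {ch.fs for ch in self.channels.values()}
        if len(fs_values) != 1:
            raise ValidationError(f"all channels must share one sampling rate, got {fs_values}")
        lengths = {ch.n for ch in self.channels.values()}
        if len(lengths) != 1:
            raise ValidationError(f"all channels must share one length, got {lengths}")
        for name, ch in self.channels.items():
            expected = _expected_units(name)
            if ch.units is not expected:
                raise ValidationError(
                    f"channel {name!r} has units {ch.units.value!r}, expected {expected.value!r}"
                )
        self._check_required_channels()

    def _check_required_channels(self) -> None:
        missing: list[str] = []
        if self.condition in RUNNING_CONDITIONS:
            for req in ("accel_foot", "accel_neck_vert"):
                if req not in self.channels:
                    missing.append(req)
        elif self.condition in JUMP_CONDITIONS:
            if FORCE_CHANNEL not in self.channels:
                missing.append(FORCE_CHANNEL)
        if missing:
            raise ValidationError(
                f"condition {self.condition.value!r} requires channels {missing}"
            )

    @property
    def fs(self) -> float:
        return next(iter(self.channels.values())).fs

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).n

    def emg_channels(self) -> dict[str, ChannelTrace]:
        return {k: v for k, v in self.channels.items() if v.units is Units.VOLTS}


class EventKind(str, Enum):
    FOOT_STRIKES = "foot_strikes"
    JUMP_PHASES = "jump_phases"


@dataclass
class EventSet:
    """Ordered sample indices that define analysis windows.

    ``foot_strikes``: one index per right-foot touch-down.
    ``jump_phases``: exactly (onset, takeoff, landing).
    """

    kind: EventKind
    times: np.ndarray
    n_samples: int | None = None

    def __post_init__(self) -> None:
        self.kind = EventKind(self.kind)
        self.times = np.asarray(self.times, dtype=int)
        if self.times.size < 1:
            raise ValidationError("event set must contain at least one event")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("event indices must be strictly increasing")
        if np.any(self.times < 0):
            raise ValidationError("event indices must be non-negative")
        if self.n_samples is not None and np.any(self.times >= self.n_samples):
            raise ValidationError("event indices must lie within the trial")
        if self.kind is EventKind.JUMP_PHASES and self.times.size != 3:
            raise ValidationError("jump phases require exactly onset < takeoff < landing")

    @property
    def onset(self) -> int:
        self._require_jump()
        return int(self.times[0])

    @property
    def takeoff(self) -> int:
        self._require_jump()
        return int(self.times[1])

    @property
    def landing(self) -> int:
        self._require_jump()
        return int(self.times[2])

    def _require_jump(self) -> None:
        if self.kind is not EventKind.JUMP_PHASES:
            raise ValidationError("not a jump-phase event set")


# ---------------------------------------------------------------------------
# Trial bundle I/O: <stem>.tsv + <stem>.meta.json
# ---------------------------------------------------------------------------

_TSV_FLOAT_FORMAT = "%.10g"


def write_trial(trial: Trial, path: str | Path) -> None:
    """Write ``trial`` as a TSV matrix plus JSON metadata sidecar.

    Columns hold *raw* (uncalibrated) values; ``read_trial`` re-applies the
    per-channel calibration, so the round trip is lossless to the
    serialization precision (10 significant digits).
    """
    path = Path(path)
    if path.suffix != ".tsv":
        path = path.with_suffix(".tsv")
    columns = {}
    meta_channels = {}
    for name, ch in trial.channels.items():
        columns[name] = ch.calibration.invert(ch.samples)
        meta_channels[name] = {
            "units": ch.units.value,
            "gain": ch.calibration.gain,
            "offset": ch.calibration.offset,
        }
    meta = {
        "subject_id": trial.subject_id,
        "condition": trial.condition.value,
        "fs": trial.fs,
        "body_mass": trial.body_mass,
        "head_added_mass": trial.head_added_mass,
        "applied_force": trial.applied_force,
        "effort_pct": trial.effort_pct,
        "channels": meta_channels,
    }
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False, float_format=_TSV_FLOAT_FORMAT)
    sidecar = path.with_name(path.stem + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=1))


def read_trial(path: str | Path) -> Trial:
    """Read a trial bundle written by :func:`write_trial`.

    Raises :class:`FormatError` if the sidecar is missing or malformed and
    :class:`ValidationError` if the resulting trial violates an invariant.
    """
    path = Path(path)
    sidecar = path.with_name(path.stem + ".meta.json")
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:  # pragma: no cover - corrupt file
        raise FormatError(f"unparseable sidecar {sidecar}: {exc}") from exc
    if "channels" not in meta or "fs" not in meta:
        raise FormatError(f"sidecar {sidecar} lacks required keys")
    frame = pd.read_csv(path, sep="\t")
    if frame.isna().any().any():
        raise ValidationError(f"channel length mismatch / missing values in {path}")
    fs = float(meta["fs"])
    channels = {}
    for name, info in meta["channels"].items():
        if name not in frame.columns:
            raise FormatError(f"channel {name!r} in sidecar but not in {path}")
        cal = Calibration(gain=float(info.get("gain", 1.0)), offset=float(info.get("offset", 0.0)))
        channels[name] = ChannelTrace(
            samples=cal.apply(frame[name].to_numpy(dtype=float)),
            fs=fs,
            units=Units(info["units"]),
            calibration=cal,
        )
    return Trial(
        subject_id=str(meta["subject_id"]),
        condition=Condition(meta["condition"]),
        channels=channels,
        body_mass=float(meta["body_mass"]),
        head_added_mass=float(meta.get("head_added_mass", 0.0)),
        applied_force=float(meta.get("applied_force", 0.0)),
        effort_pct=None if meta.get("effort_pct") is None else float(meta["effort_pct"]),
    )


def validate_applied_force(
    trial: Trial, min_n: float = 150.0, max_n: float = 200.0
) -> bool:
    """Accept/reject a pull trial on its applied horizontal force.

    The protocol rejects a trial if the applied force ever drops below
    ``min_n`` or exceeds ``max_n`` (defaults 150/200 N).  Accepts either a
    continuously logged force channel (``applied_force``) or the scalar
    per-trial value.  Returns True (accept) or False (reject).
    """
    if APPLIED_FORCE_CHANNEL in trial.channels:
        series = trial.channels[APPLIED_FORCE_CHANNEL].samples
    elif trial.applied_force:
        series = np.asarray([trial.applied_force], dtype=float)
    elif trial.condition in PULL_CONDITIONS:
        raise ValidationError(
            f"pull condition {trial.condition.value!r} carries no applied-force record"
        )
    else:
        return True
    return bool(np.all(series >= min_n) and np.all(series <= max_n))


# ---------------------------------------------------------------------------
# Study manifest (YAML) and in-memory study container
# ---------------------------------------------------------------------------


@dataclass
class StudyManifest:
    """Per-subject trial file paths keyed by condition, plus electrode mask.

    ``trials[subject][condition]`` is a list of paths relative to the
    manifest location.  ``availability[muscle]`` lists the subjects whose
    electrode for that muscle was usable; a missing key means all subjects.
    """

    subjects: list[str]
    trials: dict[str, dict[str, list[str]]]
    availability: dict[str, list[str]] = field(default_factory=dict)

    def available_subjects(self, muscle: str) -> list[str]:
        if muscle in self.availability:
            return [s for s in self.subjects if s in self.availability[muscle]]
        return list(self.subjects)

    def save(self, path: str | Path) -> None:
        payload = {
            "subjects": list(self.subjects),
            "trials": {s: {c: list(p) for c, p in conds.items()} for s, conds in self.trials.items()},
            "availability": {m: list(s) for m, s in self.availability.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "StudyManifest":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict) or "subjects" not in payload:
            raise FormatError(f"{path} is not a study manifest")
        return cls(
            subjects=[str(s) for s in payload["subjects"]],
            trials={
                str(s): {str(c): [str(p) for p in paths] for c, paths in conds.items()}
                for s, conds in payload.get("trials", {}).items()
            },
            availability={
                str(m): [str(s) for s in subs]
                for m, subs in (payload.get("availability") or {}).items()
            },
        )


@dataclass
class Study:
    """In-memory study: trials grouped by subject and condition.

    ``trials[subject][condition]`` is a list of :class:`Trial` (running
    conditions usually hold one trial, jump conditions several repeats).
    ``truth`` optionally carries generator ground truth keyed like trials.
    """

    subjects: list[str]
    trials: dict[str, dict[Condition, list[Trial]]]
    availability: dict[str, list[str]] = field(default_factory=dict)
    truth: dict | None = None

    def get(self, subject: str, condition: Condition | str) -> list[Trial]:
        return self.trials.get(subject, {}).get(Condition(condition), [])

    def available_subjects(self, muscle: str) -> list[str]:
        if muscle in self.availability:
            return [s for s in self.subjects if s in self.availability[muscle]]
        return list(self.subjects)

    def conditions(self) -> set[Condition]:
        out: set[Condition] = set()
        for conds in self.trials.values():
            out.update(conds.keys())
        return out


def load_study(manifest_path: str | Path) -> Study:
    """Materialize a :class:`Study` by reading every trial in a manifest."""
    manifest_path = Path(manifest_path)
    manifest = StudyManifest.load(manifest_path)
    root = manifest_path.parent
    trials: dict[str, dict[Condition, list[Trial]]] = {}
    for subject, conds in manifest.trials.items():
        trials[subject] = {}
        for cond_name, paths in conds.items():
            cond = Condition(cond_name)
            loaded = []
            for rel in paths:
                p = root / rel
                if not p.exists():
                    raise FormatError(f"manifest references missing file {p}")
                loaded.append(read_trial(p))
            trials[subject][cond] = loaded
    return Study(subjects=manifest.subjects, trials=trials, availability=manifest.availability)
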