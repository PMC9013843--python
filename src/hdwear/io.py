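"""Reading, writing and segmenting wearable-sensor recordings.

The on-disk layout is deliberately plain so the pipeline is self-contained:

* one CSV per (sensor location, signal kind) with columns ``t,x,y,z``
  (seconds; g or m/s^2 for accelerometers, deg/s for gyroscopes);
* one JSON manifest per subject listing the eight recordings and the seven
  task annotations (sit, stand, five walking straightaways with turns
  excluded by construction);
* a labels CSV with group membership and the seven UHDRS-TMS subscores;
* a rectangular feature-table CSV, one row per subject.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SENSOR_LOCATIONS",
    "SIGNAL_KINDS",
    "GYRO_LOCATIONS",
    "TASK_LABELS",
    "SUBSCORE_NAMES",
    "TriaxialRecording",
    "TaskSegment",
    "SessionManifest",
    "SubjectRecord",
    "SensorIOError",
    "load_recording",
    "save_recording",
    "segment_tasks",
    "load_manifest",
    "save_manifest",
    "write_feature_table",
    "read_feature_table",
    "load_labels",
    "write_labels",
]

SENSOR_LOCATIONS = (
    "left_forearm",
    "right_forearm",
    "left_thigh",
    "right_thigh",
    "sacrum",
)
SIGNAL_KINDS = ("accelerometer", "gyroscope")
#: gyroscopes exist only on the forearms and the sacrum
GYRO_LOCATIONS = ("left_forearm", "right_forearm", "sacrum")
TASK_LABELS = ("sit", "stand", "walk_1", "walk_2", "walk_3", "walk_4", "walk_5")
SUBSCORE_NAMES = (
    "arm_rigidity_left",
    "arm_rigidity_right",
    "total_chorea",
    "total_dystonia",
    "bradykinesia",
    "gait",
    "tandem_gait",
)

#: eight sensor streams per subject: five accelerometers plus three gyroscopes
SENSOR_CHANNELS = tuple(
    [(loc, "accelerometer") for loc in SENSOR_LOCATIONS]
    + [(loc, "gyroscope") for loc in GYRO_LOCATIONS]
)

MIN_SAMPLING_RATE_HZ = 32.0  # needed to support the 16 Hz band edge
MIN_SEGMENT_DURATION_S = 3.0


class SensorIOError(ValueError):
    """Raised for malformed or inconsistent sensor files and manifests."""


@dataclass(frozen=True)
class TriaxialRecording:
    """One sensor's timestamped (x, y, z) stream.

    ``t`` is in seconds and must be strictly increasing with at most 1%
    jitter around the median sampling interval; ``xyz`` is an (n, 3) array.
    """

    sensor_location: str
    signal_kind: str
    sampling_rate: float
    t: np.ndarray
    xyz: np.ndarray

    def __post_init__(self) -> None:
        if self.sensor_location not in SENSOR_LOCATIONS:
            raise SensorIOError(f"unknown sensor location {self.sensor_location!r}")
        if self.signal_kind not in SIGNAL_KINDS:
            raise SensorIOError(f"unknown signal kind {self.signal_kind!r}")
        if (
            self.signal_kind == "gyroscope"
            and self.sensor_location not in GYRO_LOCATIONS
        ):
            raise SensorIOError(
                "gyroscope recordings exist only for forearms and sacrum, "
                f"got {self.sensor_location!r}"
            )
        t = np.asarray(self.t, dtype=float)
        xyz = np.asarray(self.xyz, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xyz", xyz)
        if t.ndim != 1 or xyz.ndim != 2 or xyz.shape != (t.size, 3):
            raise SensorIOError("expected t of shape (n,) and xyz of shape (n, 3)")
        if t.size < 2:
            raise SensorIOError("recording needs at least 2 samples")
        bad = ~np.isfinite(xyz).all(axis=1) | ~np.isfinite(t)
        if bad.any():
            idx = np.flatnonzero(bad)
            raise SensorIOError(
                f"non-finite samples at indices {idx[:10].tolist()}"
                + ("..." if idx.size > 10 else "")
            )
        dt = np.diff(t)
        if (dt <= 0).any():
            idx = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise SensorIOError(f"timestamps not strictly increasing at index {idx}")
        med = float(np.median(dt))
        if np.abs(dt - med).max() > 0.01 * med + 1e-12:
            raise SensorIOError("timestamp jitter exceeds 1% of the median interval")
        if not np.isclose(self.sampling_rate, 1.0 / med, rtol=0.01):
            raise SensorIOError(
                f"sampling_rate {self.sampling_rate} inconsistent with median dt {med}"
            )
        if self.sampling_rate < MIN_SAMPLING_RATE_HZ:
            raise SensorIOError(
                f"sampling rate {self.sampling_rate:.1f} Hz is below the "
                f"{MIN_SAMPLING_RATE_HZ:.0f} Hz minimum required for the 16 Hz band edge"
            )

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def __len__(self) -> int:
        return self.t.size


@dataclass(frozen=True)
class TaskSegment:
    """A labelled, turn-free window cut from one recording."""

    task_label: str
    recording: TriaxialRecording
    start_s: float
    end_s: float
    too_short: bool = False

    @property
    def sampling_rate(self) -> float:
        return self.recording.sampling_rate


@dataclass(frozen=True)
class SessionManifest:
    """Per-subject index of sensor files and task annotations."""

    subject_id: str
    recordings: Mapping[tuple[str, str], str]  # (location, kind) -> relative path
    task_annotations: Sequence[tuple[str, float, float]]

    def __post_init__(self) -> None:
        keys = set(self.recordings)
        if keys != set(SENSOR_CHANNELS):
            missing = sorted(set(SENSOR_CHANNELS) - keys)
            extra = sorted(keys - set(SENSOR_CHANNELS))
            raise SensorIOError(
                f"manifest must list exactly 8 recordings (5 accel + 3 gyro); "
                f"missing {missing}, unexpected {extra}"
            )
        labels = [a[0] for a in self.task_annotations]
        if sorted(labels) != sorted(TASK_LABELS):
            raise SensorIOError(
                f"manifest must carry exactly the 7 task annotations {TASK_LABELS}, "
                f"got {labels}"
            )
        spans = sorted((float(a[1]), float(a[2]), a[0]) for a in self.task_annotations)
        for (s0, e0, l0), (s1, e1, l1) in zip(spans, spans[1:]):
            if e0 <= s0 or e1 <= s1:
                raise SensorIOError("task annotation with non-positive duration")
            if s1 < e0:
                raise SensorIOError(f"task annotations {l0!r} and {l1!r} overlap")


@dataclass(frozen=True)
class SubjectRecord:
    """Group label, the seven UHDRS-TMS subscores and optional covariates."""

    subject_id: str
    group: str  # "control" | "hd"
    subscores: Mapping[str, int]
    composite: int
    age: float | None = None
    total_tms: int | None = None

    def __post_init__(self) -> None:
        if self.group not in ("control", "hd"):
            raise SensorIOError(f"group must be 'control' or 'hd', got {self.group!r}")
        if set(self.subscores) != set(SUBSCORE_NAMES):
            raise SensorIOError(
                f"expected subscores {SUBSCORE_NAMES}, got {sorted(self.subscores)}"
            )
        from .models import SUBSCORE_SPECS  # local import avoids a cycle

        for name, value in self.subscores.items():
            r = SUBSCORE_SPECS[name].range
            if not (0 <= int(value) <= r):
                raise SensorIOError(f"subscore {name}={value} outside [0, {r}]")
        if self.composite != sum(int(v) for v in self.subscores.values()):
            raise SensorIOError("composite must equal the sum of the 7 subscores")
        if self.group == "control" and any(v != 0 for v in self.subscores.values()):
            raise SensorIOError("controls must have all subscores equal to zero")


# ---------------------------------------------------------------------------
# recordings


def load_recording(path: str | Path, location: str, kind: str) -> TriaxialRecording:
    """Read a ``t,x,y,z`` CSV and return a validated recording.

    The sampling rate is inferred from the median timestamp interval.
    """
    path = Path(path)
    if not path.exists():
        raise SensorIOError(f"sensor file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SensorIOError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        raise SensorIOError(f"empty sensor file: {path}")
    expected = ["t", "x", "y", "z"]
    if list(df.columns[:4]) != expected:
        raise SensorIOError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    for col in expected:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[~pd.to_numeric(df[col], errors="coerce").notna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise SensorIOError(f"{path}: non-numeric value in column {col!r} at line {line}")
    t = df["t"].to_numpy(float)
    xyz = df[["x", "y", "z"]].to_numpy(float)
    if t.size < 2:
        raise SensorIOError(f"{path}: recording needs at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return TriaxialRecording(location, kind, fs, t, xyz)


def save_recording(recording: TriaxialRecording, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "t": recording.t,
            "x": recording.xyz[:, 0],
            "y": recording.xyz[:, 1],
            "z": recording.xyz[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def segment_tasks(
    recording: TriaxialRecording,
    manifest: SessionManifest,
    min_duration_s: float = MIN_SEGMENT_DURATION_S,
) -> list[TaskSegment]:
    """Cut one recording into the seven task segments.

    Windows are half-open ``[start, end)``.  Segments shorter than
    ``min_duration_s`` are flagged (``too_short=True``) with a warning.
    """
    t0, t1 = float(recording.t[0]), float(recording.t[-1])
    segments = []
    for label, start, end in manifest.task_annotations:
        if start < t0 - 1e-9 or end > t1 + 1.0 / recording.sampling_rate + 1e-9:
            raise SensorIOError(
                f"annotation {label!r} [{start}, {end}) outside recording span "
                f"[{t0}, {t1}]"
            )
        mask = (recording.t >= start) & (recording.t < end)
        sub = TriaxialRecording(
            recording.sensor_location,
            recording.signal_kind,
            recording.sampling_rate,
            recording.t[mask],
            recording.xyz[mask],
        )
        short = (end - start) < min_duration_s
        if short:
            warnings.warn(
                f"segment {label!r} of {manifest.subject_id} is shorter than "
                f"{min_duration_s} s",
                stacklevel=2,
            )
        segments.append(TaskSegment(label, sub, float(start), float(end), short))
    order = {lab: i for i, lab in enumerate(TASK_LABELS)}
    segments.sort(key=lambda s: order[s.task_label])
    return segments


# ---------------------------------------------------------------------------
# manifests


def save_manifest(manifest: SessionManifest, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "subject_id": manifest.subject_id,
        "recordings": [
            {"location": loc, "kind": kind, "path": rel}
            for (loc, kind), rel in sorted(manifest.recordings.items())
        ],
        "task_annotations": [
            {"task": lab, "start_s": s, "end_s": e}
            for lab, s, e in manifest.task_annotations
        ],
    }
    path.write_text(json.dumps(payload, indent=1) + "\n")


def load_manifest(path: str | Path) -> SessionManifest:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SensorIOError(f"cannot parse manifest {path}: {exc}") from exc
    recordings = {
        (r["location"], r["kind"]): r["path"] for r in payload["recordings"]
    }
    annotations = [
        (a["task"], float(a["start_s"]), float(a["end_s"]))
        for a in payload["task_annotations"]
    ]
    return SessionManifest(payload["subject_id"], recordings, annotations)


# ---------------------------------------------------------------------------
# feature tables and labels


def write_feature_table(
    features: Iterable["FeatureVector"], path: str | Path  # noqa: F821
) -> None:
    """Write per-subject feature vectors to a rectangular CSV.

    All vectors must share the identical canonical feature-name ordering.
    Values are written as decimal text with 17 significant digits so a
    round-trip read reproduces them bit-exactly.
    """
    features = list(features)
    if not features:
        raise SensorIOError("no feature vectors to write")
    names = list(features[0].entries)
    for fv in features[1:]:
        if list(fv.entries) != names:
            raise SensorIOError(
                f"inconsistent feature names for subject {fv.subject_id!r}"
            )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("subject_id," + ",".join(names) + "\n")
        for fv in features:
            vals = ",".join(format(v, ".17g") for v in fv.entries.values())
            fh.write(f"{fv.subject_id},{vals}\n")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature-table CSV into a DataFrame indexed by subject id."""
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise SensorIOError(f"{path}: missing subject_id column")
    return df.set_index("subject_id")


def write_labels(records: Iterable[SubjectRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row: dict[str, object] = {"subject_id": rec.subject_id, "group": rec.group}
        row.update({name: int(rec.subscores[name]) for name in SUBSCORE_NAMES})
        row["composite"] = rec.composite
        row["age"] = rec.age if rec.age is not None else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_labels(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    records = []
    for _, row in df.iterrows():
        age = row.get("age")
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                subscores={name: int(row[name]) for name in SUBSCORE_NAMES},
                composite=int(row["composite"]),
                age=float(age) if age not in (None, "") and pd.notna(age) else None,
            )
        )
    return records
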