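"""Reading, writing and basic derivation for shank-worn IMU recordings.

A recording is the raw output of a single tri-axial accelerometer (in g)
plus tri-axial gyroscope (in deg/s) worn on the anterior shin, sampled on a
uniform grid (102.4 Hz by default).  Sensor frame convention, used
consistently by the synthetic generator and documented in every file
header: x runs along the shin (distal), y is mediolateral, z is
anterior-posterior (out of the shin).  At rest with the shin horizontal the
accelerometer reads (0, 0, 1) g.

Files are plain text: comma-separated recordings with a ``#``-prefixed
metadata header, and JSON annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

EXERCISES = ("HS", "IRQ", "SLR", "SAKE")
LABELS = ("correct", "sub_optimal")

DEFAULT_SAMPLE_RATE = 102.4

_CSV_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]


class FormatError(ValueError):
    """Raised when a file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """Raised when in-memory data violate a structural invariant."""


@dataclass
class ImuRecording:
    """Six-channel inertial time series with identity metadata.

    accel is an (N, 3) array in g; gyro an (N, 3) array in deg/s.
    """

    subject_id: str
    exercise: str
    session_id: str
    accel: np.ndarray
    gyro: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.exercise not in EXERCISES:
            raise ValidationError(f"unknown exercise {self.exercise!r}")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValidationError("accel must be an (N, 3) array")
        if self.gyro.shape != self.accel.shape:
            raise ValidationError("gyro and accel must have the same shape")
        if self.accel.shape[0] < 1:
            raise ValidationError("recording must contain at least one sample")
        if not (np.isfinite(self.accel).all() and np.isfinite(self.gyro).all()):
            raise ValidationError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImuRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.exercise == other.exercise
            and self.session_id == other.session_id
            and self.sample_rate == other.sample_rate
            and np.array_equal(self.accel, other.accel)
            and np.array_equal(self.gyro, other.gyro)
        )


@dataclass
class DerivedSignals:
    """The nine analysis vectors used throughout the pipeline.

    The six raw channels are copied verbatim; ``magnitude`` is the
    acceleration magnitude in g (gravity-anchored, so ~1 at rest);
    ``pitch``/``roll`` are accelerometer tilt angles in radians.
    """

    accel_x: np.ndarray
    accel_y: np.ndarray
    accel_z: np.ndarray
    gyro_x: np.ndarray
    gyro_y: np.ndarray
    gyro_z: np.ndarray
    magnitude: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE

    NAMES = (
        "accel_x", "accel_y", "accel_z",
        "gyro_x", "gyro_y", "gyro_z",
        "magnitude", "pitch", "roll",
    )

    def vector(self, name: str) -> np.ndarray:
        if name not in self.NAMES:
            raise KeyError(name)
        return getattr(self, name)

    @property
    def n_samples(self) -> int:
        return self.accel_x.shape[0]

    def gyro_magnitude(self) -> np.ndarray:
        return np.sqrt(self.gyro_x**2 + self.gyro_y**2 + self.gyro_z**2)


@dataclass(frozen=True)
class Repetition:
    """One repetition as a half-open sample interval [start, end)."""

    start: int
    end: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"repetition bounds must satisfy 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.label is not None and self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class SegmentAnnotation:
    """Ordered, non-overlapping repetition boundaries, optionally labelled."""

    reps: list[Repetition] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reps = [r if isinstance(r, Repetition) else Repetition(**r) for r in self.reps]
        for prev, cur in zip(self.reps, self.reps[1:]):
            if cur.start < prev.end:
                raise ValidationError(
                    f"repetitions overlap or are unsorted: [{prev.start},{prev.end}) then "
                    f"[{cur.start},{cur.end})"
                )

    def __len__(self) -> int:
        return len(self.reps)

    def __iter__(self):
        return iter(self.reps)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentAnnotation):
            return NotImplemented
        return self.reps == other.reps

    def starts(self) -> np.ndarray:
        return np.array([r.start for r in self.reps], dtype=int)

    def ends(self) -> np.ndarray:
        return np.array([r.end for r in self.reps], dtype=int)

    def labels(self) -> list[Optional[str]]:
        return [r.label for r in self.reps]


# ---------------------------------------------------------------------------
# recording I/O

def write_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write a recording as CSV with a ``#`` metadata header.

    Values are written with 17 significant digits so the round trip through
    :func:`read_recording` is value-exact.
    """
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.sample_rate
    with open(path, "w") as fh:
        fh.write("# imurehab recording v1\n")
        fh.write(f"# subject_id: {rec.subject_id}\n")
        fh.write(f"# exercise: {rec.exercise}\n")
        fh.write(f"# session_id: {rec.session_id}\n")
        fh.write(f"# sample_rate_hz: {rec.sample_rate!r}\n")
        fh.write("# frame: x along shin (distal), y mediolateral, z anterior; accel g, gyro deg/s\n")
        fh.write(",".join(_CSV_COLUMNS) + "\n")
        data = np.column_stack([t, rec.accel, rec.gyro])
        for row in data:
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")


def read_recording(path: str | Path) -> ImuRecording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`FormatError` for malformed headers or missing columns and
    :class:`ValidationError` for timestamp jitter above 1% of the sample
    period.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    required = ("subject_id", "exercise", "session_id", "sample_rate_hz")
    missing = [k for k in required if k not in meta]
    if missing:
        raise FormatError(f"recording header missing metadata: {missing}")
    try:
        sample_rate = float(meta["sample_rate_hz"])
    except ValueError as exc:
        raise FormatError(f"bad sample_rate_hz: {meta['sample_rate_hz']!r}") from exc

    df = pd.read_csv(path, skiprows=header_lines, float_precision="round_trip")
    if list(df.columns) != _CSV_COLUMNS:
        raise FormatError(
            f"expected columns {_CSV_COLUMNS}, found {list(df.columns)}"
        )
    if len(df) < 1:
        raise FormatError("recording contains no samples")
    t = df["t"].to_numpy(dtype=float)
    if len(t) > 1:
        dt = np.diff(t)
        period = 1.0 / sample_rate
        if np.any(np.abs(dt - period) > 0.01 * period):
            raise ValidationError("non-uniform timestamps beyond 1% jitter")
    return ImuRecording(
        subject_id=meta["subject_id"],
        exercise=meta["exercise"],
        session_id=meta["session_id"],
        accel=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(dtype=float),
        sample_rate=sample_rate,
    )


# ---------------------------------------------------------------------------
# annotation I/O

def write_annotations(ann: SegmentAnnotation, path: str | Path) -> None:
    payload = {
        "reps": [
            {"start": int(r.start), "end": int(r.end)}
            | ({"label": r.label} if r.label is not None else {})
            for r in ann.reps
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_annotations(path: str | Path) -> SegmentAnnotation:
    with open(path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, dict) or "reps" not in payload:
        raise FormatError("annotation file must be a JSON object with a 'reps' list")
    reps = [
        Repetition(start=int(r["start"]), end=int(r["end"]), label=r.get("label"))
        for r in payload["reps"]
    ]
    return SegmentAnnotation(reps=reps)


# ---------------------------------------------------------------------------
# derived signals

def derive_signals(rec: ImuRecording) -> DerivedSignals:
    """Compute the nine analysis vectors from a raw recording.

    magnitude[i] = ||accel[i]||; pitch = atan2(-ax, sqrt(ay^2 + az^2)) and
    roll = atan2(ay, az) are the standard accelerometer-only static-tilt
    angles for this sensor frame (no gyro fusion).
    """
    ax, ay, az = rec.accel[:, 0], rec.accel[:, 1], rec.accel[:, 2]
    magnitude = np.sqrt(ax**2 + ay**2 + az**2)
    pitch = np.arctan2(-ax, np.sqrt(ay**2 + az**2))
    roll = np.arctan2(ay, az)
    return DerivedSignals(
        accel_x=ax.copy(),
        accel_y=ay.copy(),
        accel_z=az.copy(),
        gyro_x=rec.gyro[:, 0].copy(),
        gyro_y=rec.gyro[:, 1].copy(),
        gyro_z=rec.gyro[:, 2].copy(),
        magnitude=magnitude,
        pitch=pitch,
        roll=roll,
        sample_rate=rec.sample_rate,
    )
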