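"""Synthetic annotated IMU exercise sessions.

The generator emulates the data a shank-worn IMU produces while a person
performs sets of lower-limb rehabilitation exercises lying or sitting at
home: discrete repetitions — smooth raised-cosine tilt excursions about the
mediolateral axis, hence biphasic angular-velocity pulses on gyro y —
separated by near-still rest, with per-subject tempo/amplitude effects,
per-session baseline orientation offsets, sensor noise, and injectable
technique deviations (one characteristic error mode per exercise).

Three presets describe the study conditions the pipeline is validated
under: a supervised-clinic ``training`` cohort (balanced labels, low
noise), a ``healthy`` home test cohort (all-correct technique, moderate
noise/variability), and a ``clinical`` post-surgery home cohort (slower,
weaker, noisier and more variable movement, mixed labels, three sets per
subject).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import (
    DEFAULT_SAMPLE_RATE,
    EXERCISES,
    ImuRecording,
    Repetition,
    SegmentAnnotation,
    ValidationError,
)

ERROR_MODES = (
    "hip_external_rotation",   # HS: leg rolls outward during the slide
    "hip_flexion_lift",        # IRQ: knee lifts off the support roll
    "knee_flexion_lag",        # SLR: knee sags mid-raise
    "incomplete_extension",    # SAKE: terminal extension range truncated
)

#: The one deviation assessed per exercise.
EXERCISE_ERROR_MODE = {
    "HS": "hip_external_rotation",
    "IRQ": "hip_flexion_lift",
    "SLR": "knee_flexion_lag",
    "SAKE": "incomplete_extension",
}

#: Peak pitch excursion (rad) of a nominal correct repetition, per exercise.
#: Rough joint-excursion scale as seen by a shin-mounted sensor: heel slides
#: and leg raises sweep the shank through a large tilt; inner-range quads
#: work over a smaller arc.
EXERCISE_PITCH_AMPLITUDE = {
    "HS": 0.9,
    "IRQ": 0.55,
    "SLR": 0.75,
    "SAKE": 0.85,
}


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class DeviationModel:
    """A technique deviation to inject into a clean repetition."""

    exercise: str
    error_mode: str
    severity: float

    def __post_init__(self) -> None:
        if self.error_mode not in ERROR_MODES:
            raise ConfigurationError(f"unknown error_mode {self.error_mode!r}")
        if EXERCISE_ERROR_MODE.get(self.exercise) != self.error_mode:
            raise ConfigurationError(
                f"error_mode {self.error_mode!r} does not match exercise {self.exercise!r}"
            )
        if not (0.0 < self.severity <= 1.0):
            raise ConfigurationError("severity must lie in (0, 1]")


@dataclass(frozen=True)
class RepKinematics:
    """Pitch/roll angle trajectories (rad) of one repetition."""

    pitch: np.ndarray
    roll: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.pitch.shape[0]


@dataclass
class CohortConfig:
    """Generator parameters for one cohort.

    Durations in seconds, accelerometer noise in g, gyroscope noise in
    deg/s.  ``amplitude_mean`` is a dimensionless multiplier on the
    per-exercise nominal pitch excursion; ``subject_variability_scale``
    scales the between-subject tempo/amplitude random effects;
    ``orientation_sd`` (rad) is the SD of the per-session baseline
    pitch/roll offset (how reproducibly the sleeve is donned and how level
    the support surface is).
    """

    n_subjects: int = 10
    reps_per_set: int = 15
    sets_per_subject: int = 1
    sub_optimal_fraction: float = 0.0
    rep_duration_mean: float = 3.0
    rep_duration_sd: float = 0.3
    rest_duration_mean: float = 2.0
    rest_duration_sd: float = 0.3
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.08
    noise_sd_accel: float = 0.02
    noise_sd_gyro: float = 1.0
    subject_variability_scale: float = 1.0
    orientation_sd: float = 0.03
    severity: float = 0.7
    sample_rate: float = DEFAULT_SAMPLE_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rep_duration_sd", "rest_duration_sd", "amplitude_sd",
                     "noise_sd_accel", "noise_sd_gyro"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.rep_duration_mean <= 0 or self.rest_duration_mean <= 0:
            raise ValidationError("durations must be positive")
        if not (0.0 <= self.sub_optimal_fraction <= 1.0):
            raise ValidationError("sub_optimal_fraction must lie in [0, 1]")
        if not (0.0 < self.severity <= 1.0):
            raise ValidationError("severity must lie in (0, 1]")
        if self.n_subjects < 1 or self.reps_per_set < 1 or self.sets_per_subject < 1:
            raise ValidationError("counts must be >= 1")


def training_preset(n_subjects: int = 10, seed: int = 0) -> CohortConfig:
    """Supervised-clinic training conditions: balanced labels, low noise."""
    return CohortConfig(
        n_subjects=n_subjects,
        sets_per_subject=2,
        sub_optimal_fraction=0.5,
        rep_duration_mean=3.0, rep_duration_sd=0.3,
        rest_duration_mean=2.0, rest_duration_sd=0.3,
        amplitude_mean=1.0, amplitude_sd=0.08,
        noise_sd_accel=0.02, noise_sd_gyro=1.2,
        subject_variability_scale=1.0,
        orientation_sd=0.02,
        seed=seed,
    )


def healthy_preset(n_subjects: int = 10, seed: int = 0) -> CohortConfig:
    """Healthy home-test conditions: all-correct technique, moderate noise."""
    return CohortConfig(
        n_subjects=n_subjects,
        sets_per_subject=1,
        sub_optimal_fraction=0.0,
        rep_duration_mean=2.8, rep_duration_sd=0.35,
        rest_duration_mean=2.0, rest_duration_sd=0.4,
        amplitude_mean=1.0, amplitude_sd=0.08,
        noise_sd_accel=0.025, noise_sd_gyro=1.5,
        subject_variability_scale=1.2,
        orientation_sd=0.05,
        seed=seed,
    )


def clinical_preset(n_subjects: int = 10, seed: int = 0) -> CohortConfig:
    """Post-surgery home conditions: slower, weaker, noisier, mixed labels."""
    return CohortConfig(
        n_subjects=n_subjects,
        sets_per_subject=3,
        sub_optimal_fraction=0.4,
        rep_duration_mean=3.8, rep_duration_sd=0.7,
        rest_duration_mean=2.2, rest_duration_sd=0.6,
        amplitude_mean=0.8, amplitude_sd=0.2,
        noise_sd_accel=0.05, noise_sd_gyro=3.5,
        subject_variability_scale=2.0,
        orientation_sd=0.12,
        seed=seed,
    )


PRESETS = {
    "training": training_preset,
    "healthy": healthy_preset,
    "clinical": clinical_preset,
}


# ---------------------------------------------------------------------------
# waveforms

def _raised_cosine(n: int) -> np.ndarray:
    """Raised-cosine bump on [0, 1): 0 at the edges, 1 at the centre."""
    u = np.arange(n) / n
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * u))


def _centered_window(n: int, center: float, width: float) -> np.ndarray:
    """Raised-cosine window of relative `width` centered at relative `center`."""
    u = np.arange(n) / n
    w = np.zeros(n)
    inside = np.abs(u - center) < width / 2.0
    w[inside] = 0.5 * (1.0 + np.cos(2.0 * np.pi * (u[inside] - center) / width))
    return w


def clean_repetition(exercise: str, n_samples: int, amplitude: float = 1.0) -> RepKinematics:
    """Kinematics of a correctly performed repetition.

    The shank tilts away from rest and back along a raised-cosine profile;
    roll stays flat for a correct repetition of any of the four exercises.
    """
    theta_max = EXERCISE_PITCH_AMPLITUDE[exercise] * amplitude
    return RepKinematics(
        pitch=theta_max * _raised_cosine(n_samples),
        roll=np.zeros(n_samples),
    )


def inject_deviation(rep: RepKinematics, model: DeviationModel) -> RepKinematics:
    """Deterministically transform a clean repetition per the error mode.

    All four transforms are continuous in severity and reduce to the
    identity as severity -> 0:

    - hip_external_rotation: a correlated roll excursion rides along the rep
      (the leg rolls outward while sliding).
    - hip_flexion_lift: an extra mid-rep pitch bump (the knee lifts off the
      support roll near peak effort).
    - knee_flexion_lag: the pitch profile sags mid-rep (the knee gives way
      part-way through the raise).
    - incomplete_extension: the whole excursion is scaled down, so peak
      range is (1 - severity) of the clean repetition's.
    """
    n = rep.n_samples
    s = model.severity
    pitch, roll = rep.pitch.copy(), rep.roll.copy()
    if model.error_mode == "hip_external_rotation":
        roll = roll + s * 0.6 * _raised_cosine(n)
    elif model.error_mode == "hip_flexion_lift":
        pitch = pitch + s * 0.45 * _centered_window(n, 0.5, 0.5)
    elif model.error_mode == "knee_flexion_lag":
        pitch = pitch * (1.0 - s * 0.55 * _centered_window(n, 0.5, 0.45))
    elif model.error_mode == "incomplete_extension":
        pitch = pitch * (1.0 - s)
    else:  # pragma: no cover - guarded by DeviationModel
        raise ConfigurationError(f"unknown error_mode {model.error_mode!r}")
    return RepKinematics(pitch=pitch, roll=roll)


def _kinematics_to_signals(
    pitch: np.ndarray, roll: np.ndarray, sample_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Map tilt trajectories to noiseless accel (g) and gyro (deg/s) channels.

    Gravity is resolved through the tilt angles; angular rates are the
    trajectory derivatives about the body axes (small-coupling
    approximation, adequate for tilt excursions under ~1 rad).
    """
    ax = -np.sin(pitch)
    ay = np.sin(roll) * np.cos(pitch)
    az = np.cos(roll) * np.cos(pitch)
    deg = 180.0 / np.pi
    gx = np.gradient(roll) * sample_rate * deg
    gy = np.gradient(pitch) * sample_rate * deg
    gz = np.zeros_like(pitch)
    return np.column_stack([ax, ay, az]), np.column_stack([gx, gy, gz])


# ---------------------------------------------------------------------------
# sessions and cohorts

def _subject_rng(config: CohortConfig, subject_id: str) -> np.random.Generator:
    # one stream per subject so cohorts are extensible without perturbing
    # existing subjects
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, zlib.crc32(subject_id.encode())])
    )


def _session_rng(
    config: CohortConfig, subject_id: str, exercise: str, set_index: int
) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            [config.seed, zlib.crc32(subject_id.encode()),
             EXERCISES.index(exercise), set_index]
        )
    )


def _truncated_normal(rng, mean, sd, low):
    v = rng.normal(mean, sd)
    return max(v, low)


def generate_session(
    config: CohortConfig, subject_id: str, exercise: str, set_index: int = 0
) -> tuple[ImuRecording, SegmentAnnotation]:
    """Generate one annotated exercise set.

    The recording holds ``reps_per_set`` repetitions separated by rest;
    annotation boundaries are the true pulse onsets/offsets.  Each
    repetition is labelled correct, or sub_optimal with the exercise's
    deviation injected, by an independent draw at ``sub_optimal_fraction``.
    Fully reproducible from ``config.seed`` and the identity arguments.
    """
    if exercise not in EXERCISES:
        raise ValidationError(f"unknown exercise {exercise!r}")
    fs = config.sample_rate
    srng = _subject_rng(config, subject_id)
    scale = config.subject_variability_scale
    tempo_mult = max(1.0 + 0.06 * scale * srng.standard_normal(), 0.5)
    amp_mult = max(1.0 + 0.06 * scale * srng.standard_normal(), 0.3)

    rng = _session_rng(config, subject_id, exercise, set_index)
    pitch0 = rng.normal(0.0, config.orientation_sd)
    roll0 = rng.normal(0.0, config.orientation_sd)

    pitch_parts: list[np.ndarray] = []
    roll_parts: list[np.ndarray] = []
    reps: list[Repetition] = []
    cursor = 0

    def add_rest() -> None:
        nonlocal cursor
        dur = _truncated_normal(rng, config.rest_duration_mean, config.rest_duration_sd, 0.8)
        n = max(int(round(dur * fs)), 1)
        pitch_parts.append(np.zeros(n))
        roll_parts.append(np.zeros(n))
        cursor += n

    add_rest()
    for _ in range(config.reps_per_set):
        dur = _truncated_normal(
            rng, config.rep_duration_mean * tempo_mult, config.rep_duration_sd, 1.0
        )
        n = max(int(round(dur * fs)), 4)
        amp = _truncated_normal(rng, config.amplitude_mean * amp_mult, config.amplitude_sd, 0.15)
        kin = clean_repetition(exercise, n, amplitude=amp)
        sub_optimal = rng.random() < config.sub_optimal_fraction
        if sub_optimal:
            kin = inject_deviation(
                kin,
                DeviationModel(
                    exercise=exercise,
                    error_mode=EXERCISE_ERROR_MODE[exercise],
                    severity=config.severity,
                ),
            )
        pitch_parts.append(kin.pitch)
        roll_parts.append(kin.roll)
        reps.append(
            Repetition(start=cursor, end=cursor + n,
                       label="sub_optimal" if sub_optimal else "correct")
        )
        cursor += n
        add_rest()

    pitch = np.concatenate(pitch_parts) + pitch0
    roll = np.concatenate(roll_parts) + roll0
    accel, gyro = _kinematics_to_signals(pitch, roll, fs)
    accel = accel + rng.normal(0.0, config.noise_sd_accel, accel.shape)
    gyro = gyro + rng.normal(0.0, config.noise_sd_gyro, gyro.shape)

    rec = ImuRecording(
        subject_id=subject_id,
        exercise=exercise,
        session_id=f"{subject_id}-{exercise}-set{set_index}",
        accel=accel,
        gyro=gyro,
        sample_rate=fs,
    )
    return rec, SegmentAnnotation(reps=reps)


@dataclass
class SessionRecord:
    """One generated set with its identity and ground truth."""

    cohort: str
    subject_id: str
    exercise: str
    set_index: int
    recording: ImuRecording
    annotation: SegmentAnnotation


def generate_cohort(
    config: CohortConfig,
    cohort: str = "custom",
    exercises: tuple[str, ...] = EXERCISES,
    subject_prefix: Optional[str] = None,
) -> list[SessionRecord]:
    """Generate every (subject, exercise, set) session for a cohort config.

    ``cohort`` is a tag carried into the manifest; pass a preset name
    through :func:`PRESETS` to obtain the matching config.
    """
    prefix = subject_prefix if subject_prefix is not None else cohort[:1].upper() or "S"
    sessions: list[SessionRecord] = []
    for i in range(config.n_subjects):
        subject_id = f"{prefix}{i + 1:02d}"
        for exercise in exercises:
            for set_index in range(config.sets_per_subject):
                rec, ann = generate_session(config, subject_id, exercise, set_index)
                sessions.append(
                    SessionRecord(
                        cohort=cohort,
                        subject_id=subject_id,
                        exercise=exercise,
                        set_index=set_index,
                        recording=rec,
                        annotation=ann,
                    )
                )
    return sessions


def write_cohort(sessions: list[SessionRecord], out_dir) -> dict:
    """Write a cohort to disk (CSV recordings + JSON annotations + manifest).

    Returns the manifest dict, also written as ``manifest.json``.
    """
    import json
    from pathlib import Path

    from .io import write_annotations, write_recording

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in sessions:
        stem = f"{s.subject_id}_{s.exercise}_set{s.set_index}"
        rec_path = out_dir / f"{stem}.csv"
        ann_path = out_dir / f"{stem}.json"
        write_recording(s.recording, rec_path)
        write_annotations(s.annotation, ann_path)
        entries.append(
            {
                "cohort": s.cohort,
                "subject_id": s.subject_id,
                "exercise": s.exercise,
                "set_index": s.set_index,
                "recording": rec_path.name,
                "annotation": ann_path.name,
                "n_reps": len(s.annotation),
            }
        )
    manifest = {"sessions": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")
    return manifest
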