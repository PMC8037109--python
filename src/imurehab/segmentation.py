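"""Template-matching repetition segmentation.

The segmenter works in three stages: (1) find rest — maximal spans where a
moving standard deviation of the gyroscope magnitude stays below a
threshold (the gyroscope is near-zero at rest regardless of orientation,
unlike the accelerometer); (2) cluster nearby rest spans and take each
cluster's midpoint as a reference point; (3) for every pair of consecutive
reference points, trim the enclosed span to its activity onset/offset and
accept it as a repetition if its normalized cross-correlation against the
exercise template exceeds a threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io import DerivedSignals, Repetition, SegmentAnnotation, ValidationError


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SegmenterParams:
    """Tunables for the rest-detection / template-matching segmenter.

    rest_window — moving-SD window (s); rest_threshold — gyro-magnitude
    moving-SD level (deg/s) below which a sample counts as rest;
    min_rest_gap — rest spans closer than this (s) merge into one cluster;
    template_length — common resample length for templates and candidates;
    match_threshold — minimum normalized cross-correlation to accept a span.
    """

    rest_window: float = 1.0
    rest_threshold: float = 3.0
    min_rest_gap: float = 0.8
    template_length: int = 128
    match_threshold: float = 0.7

    def __post_init__(self) -> None:
        if self.rest_window <= 0 or self.min_rest_gap <= 0 or self.template_length < 2:
            raise ConfigurationError("window, gap and template_length must be positive")
        if self.rest_threshold < 0:
            raise ConfigurationError("rest_threshold must be >= 0")
        if not (0.0 <= self.match_threshold <= 1.0):
            raise ConfigurationError("match_threshold must lie in [0, 1]")


@dataclass
class ExerciseTemplate:
    """Unit-energy expected repetition waveform (primary-axis gyro)."""

    exercise: str
    vector: np.ndarray
    norm: float  # energy scale removed during normalization

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"exercise": self.exercise, "norm": self.norm,
                 "vector": self.vector.tolist()},
                fh,
            )
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "ExerciseTemplate":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(exercise=payload["exercise"], vector=np.array(payload["vector"]),
                   norm=payload["norm"])


# ---------------------------------------------------------------------------
# activity statistic

def moving_sd(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving standard deviation (population), edge-replicated."""
    w = max(int(window_samples), 2)
    m = uniform_filter1d(x, size=w, mode="nearest")
    m2 = uniform_filter1d(x * x, size=w, mode="nearest")
    var = np.maximum(m2 - m * m, 0.0)
    return np.sqrt(var)


def activity_profile(
    sig: DerivedSignals, params: SegmenterParams, window_scale: float = 1.0
) -> np.ndarray:
    """Moving SD of the gyro magnitude — the rest/activity statistic.

    ``window_scale`` shrinks the window for fine boundary refinement; the
    full window is used for rest detection (a long window stays high over
    the slow-velocity crest of a repetition, a short one hugs onsets).
    """
    w = int(round(params.rest_window * window_scale * sig.sample_rate))
    return moving_sd(sig.gyro_magnitude(), w)


# ---------------------------------------------------------------------------
# stages

def detect_rest_periods(
    sig: DerivedSignals, params: SegmenterParams
) -> list[tuple[int, int]]:
    """Maximal half-open intervals where the activity statistic is below
    ``rest_threshold``.  A signal entirely below threshold yields one
    full-span interval (caller decides this means "no exercise")."""
    act = activity_profile(sig, params)
    below = act < params.rest_threshold
    if not below.any():
        return []
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    bounds = np.concatenate([[0], edges + 1, [len(below)]])
    intervals = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if below[lo]:
            intervals.append((int(lo), int(hi)))
    return intervals


def cluster_rest_periods(
    intervals: Sequence[tuple[int, int]], params: SegmenterParams, sample_rate: float
) -> list[int]:
    """Merge rest intervals separated by less than ``min_rest_gap`` and
    return one reference point per cluster: the midpoint of its span."""
    if not intervals:
        return []
    gap_samples = params.min_rest_gap * sample_rate
    clusters: list[list[int]] = [[*intervals[0]]]
    for start, end in intervals[1:]:
        if start - clusters[-1][1] < gap_samples:
            clusters[-1][1] = end
        else:
            clusters.append([start, end])
    return [int((lo + hi) // 2) for lo, hi in clusters]


def _resample(v: np.ndarray, length: int) -> np.ndarray:
    # linear resampling on a normalized axis; deterministic, no spectral ringing
    src = np.linspace(0.0, 1.0, len(v))
    dst = np.linspace(0.0, 1.0, length)
    return np.interp(dst, src, v)


def build_template(
    training_reps: Sequence[np.ndarray], params: SegmenterParams, exercise: str = "HS"
) -> ExerciseTemplate:
    """Average length-normalized training repetitions into a unit-energy
    expected waveform."""
    if len(training_reps) == 0:
        raise ConfigurationError("cannot build a template from zero repetitions")
    stack = np.stack([_resample(np.asarray(r, dtype=float), params.template_length)
                      for r in training_reps])
    mean = stack.mean(axis=0)
    norm = float(np.sqrt(np.sum(mean**2)))
    if norm == 0.0:
        raise ConfigurationError("training repetitions average to a zero waveform")
    return ExerciseTemplate(exercise=exercise, vector=mean / norm, norm=norm)


def match_template(
    candidate: np.ndarray, template: ExerciseTemplate, params: SegmenterParams
) -> tuple[float, bool]:
    """Normalized cross-correlation (zero lag) of the resampled candidate
    against the template; accepted iff score >= match_threshold.

    A zero-energy candidate scores 0 and is rejected.
    """
    candidate = np.asarray(candidate, dtype=float)
    if len(candidate) < 2:
        raise ValidationError("candidate must contain at least 2 samples")
    v = _resample(candidate, params.template_length)
    energy = np.sqrt(np.sum(v**2))
    if energy == 0.0:
        return 0.0, False
    score = float(np.dot(v / energy, template.vector))
    return score, score >= params.match_threshold


def segment_session(
    sig: DerivedSignals, template: ExerciseTemplate, params: SegmenterParams
) -> SegmentAnnotation:
    """Segment a session into repetitions (unlabelled).

    Each span between consecutive reference points is trimmed to the first
    and last sample whose activity statistic exceeds ``rest_threshold``,
    then accepted if the trimmed primary-axis (gyro y) waveform matches the
    template.  Trimming uses a quarter-width activity window so boundaries
    hug the true onset/offset instead of the rest-detection window's smear.
    Fewer than two reference points — e.g. a pure-rest signal — yields an
    empty annotation.
    """
    act = activity_profile(sig, params, window_scale=0.25)
    intervals = detect_rest_periods(sig, params)
    refs = cluster_rest_periods(intervals, params, sig.sample_rate)
    reps: list[Repetition] = []
    primary = sig.gyro_y
    for lo, hi in zip(refs[:-1], refs[1:]):
        active = np.flatnonzero(act[lo:hi] >= params.rest_threshold)
        if len(active) < 2:
            continue
        start = lo + int(active[0])
        end = lo + int(active[-1]) + 1
        if end - start < 2:
            continue
        _, accepted = match_template(primary[start:end], template, params)
        if accepted:
            reps.append(Repetition(start=start, end=end))
    return SegmentAnnotation(reps=reps)
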