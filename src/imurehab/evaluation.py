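"""Metrics, the asymmetric temporal-tolerance boundary matcher, combined
system evaluation, cohort summaries and accuracy banding.

Classification of a repetition is scored with accuracy / sensitivity /
specificity on pooled confusion counts ("correct" technique is the
positive class).  Segmentation is scored by matching predicted boundary
points against manual ones inside an asymmetric temporal tolerance —
0.5 s outward, 0.25 s inward of each annotated point, with an escape
clause that accepts points even further outward as long as they do not
cross into the neighbouring repetition — then computing event precision,
recall and accuracy TP / (TP + FP + FN).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io import DerivedSignals, Repetition, SegmentAnnotation, ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp, fp=self.fp + other.fp,
            tn=self.tn + other.tn, fn=self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ToleranceConfig:
    """Asymmetric temporal tolerance around manually annotated boundaries.

    ``t_before`` is the outward slack (before a start / after an end) and
    ``t_after`` the inward slack, in seconds.
    """

    t_before: float = 0.5
    t_after: float = 0.25
    sample_rate: float = 102.4

    def __post_init__(self) -> None:
        if self.t_before < 0 or self.t_after < 0:
            raise ValidationError("tolerances must be >= 0")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")


BANDS = ("excellent", "good", "moderate", "poor")


def accuracy_band(mean_pct: float) -> str:
    """Qualitative band: excellent >= 90, good 80-89, moderate 60-79, else poor."""
    if mean_pct >= 90.0:
        return "excellent"
    if mean_pct >= 80.0:
        return "good"
    if mean_pct >= 60.0:
        return "moderate"
    return "poor"


@dataclass
class CohortSummary:
    """Mean with a 95% t-interval (clipped to [0, 100]) over evaluation units."""

    values: list[float]
    unit: str
    mean: float
    ci_lower: float
    ci_upper: float
    band: str


# ---------------------------------------------------------------------------
# metric equations

def classification_metrics(
    c: ConfusionCounts,
) -> tuple[float, Optional[float], Optional[float]]:
    """(accuracy, sensitivity, specificity) in percent.

    Sensitivity is None when there are no positive ground-truth cases,
    specificity None when there are no negative ones (an all-correct test
    set cannot measure specificity).
    """
    if c.total == 0:
        raise ValidationError("cannot compute metrics on all-zero counts")
    accuracy = 100.0 * (c.tp + c.tn) / c.total
    sensitivity = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    specificity = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return accuracy, sensitivity, specificity


def segmentation_metrics(
    c: ConfusionCounts,
) -> tuple[Optional[float], Optional[float], float]:
    """(precision, recall, accuracy) in percent for boundary events.

    Accuracy is TP / (TP + FP + FN); precision or recall is None when its
    denominator is zero.
    """
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        raise ValidationError("no boundary events to score")
    precision = 100.0 * c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    accuracy = 100.0 * c.tp / denom
    return precision, recall, accuracy


# ---------------------------------------------------------------------------
# temporal-tolerance boundary matching

def _start_valid(pred: float, k: int, starts: np.ndarray, ends: np.ndarray,
                 tb: float, ta: float) -> bool:
    """Is predicted start `pred` acceptable for manual repetition k?"""
    s = starts[k]
    if s - tb <= pred <= s + ta:
        return True
    # escape clause: even earlier is fine while it stays clear of the
    # previous repetition (first repetition: clear of the signal start)
    if pred < s - tb:
        prev_end = ends[k - 1] if k > 0 else -np.inf
        return pred > prev_end and pred >= 0
    return False


def _end_valid(pred: float, k: int, starts: np.ndarray, ends: np.ndarray,
               tb: float, ta: float) -> bool:
    """Is predicted end `pred` acceptable for manual repetition k? (mirror)"""
    e = ends[k]
    if e - ta <= pred <= e + tb:
        return True
    if pred > e + tb:
        next_start = starts[k + 1] if k + 1 < len(starts) else np.inf
        return pred < next_start
    return False


def _match_points(
    pred_pts: np.ndarray, anchors: np.ndarray, valid
) -> ConfusionCounts:
    """Greedy nearest-first one-to-one matching of predicted points to
    manual anchor points under a validity predicate valid(pred, k)."""
    pairs = []
    for j, p in enumerate(pred_pts):
        for k in range(len(anchors)):
            if valid(p, k):
                pairs.append((abs(p - anchors[k]), k, j))
    pairs.sort()
    used_manual: set[int] = set()
    used_pred: set[int] = set()
    tp = 0
    for _, k, j in pairs:
        if k in used_manual or j in used_pred:
            continue
        used_manual.add(k)
        used_pred.add(j)
        tp += 1
    return ConfusionCounts(tp=tp, fp=len(pred_pts) - tp, fn=len(anchors) - tp)


def match_boundaries(
    predicted: SegmentAnnotation,
    manual: SegmentAnnotation,
    tol: ToleranceConfig,
) -> ConfusionCounts:
    """Score predicted against manual boundaries under the asymmetric
    tolerance; start and end points are matched separately (each manual
    point can absorb at most one predicted point, nearest first) and the
    counts summed."""
    tb = tol.t_before * tol.sample_rate
    ta = tol.t_after * tol.sample_rate
    m_starts = manual.starts().astype(float)
    m_ends = manual.ends().astype(float)
    p_starts = predicted.starts().astype(float)
    p_ends = predicted.ends().astype(float)
    c_start = _match_points(
        p_starts, m_starts,
        lambda p, k: _start_valid(p, k, m_starts, m_ends, tb, ta),
    )
    c_end = _match_points(
        p_ends, m_ends,
        lambda p, k: _end_valid(p, k, m_starts, m_ends, tb, ta),
    )
    return c_start + c_end


# ---------------------------------------------------------------------------
# combined system evaluation

@dataclass
class AlignedPair:
    predicted: Repetition
    label: str


def align_segments_to_labels(
    predicted: SegmentAnnotation, manual: SegmentAnnotation
) -> tuple[list[AlignedPair], int]:
    """Pair each predicted segment with the maximally overlapping manual
    repetition (ties -> earlier; each manual repetition pairs at most
    once).  Returns the pairs plus a count of predicted segments with no
    overlap (spurious detections in rest)."""
    pairs: list[AlignedPair] = []
    claimed: set[int] = set()
    dropped = 0
    for seg in predicted:
        best_k, best_overlap = -1, 0
        for k, man in enumerate(manual):
            if k in claimed:
                continue
            overlap = min(seg.end, man.end) - max(seg.start, man.start)
            if overlap > best_overlap:
                best_k, best_overlap = k, overlap
        if best_k < 0:
            dropped += 1
            continue
        claimed.add(best_k)
        pairs.append(AlignedPair(predicted=seg, label=manual.reps[best_k].label))
    return pairs, dropped


@dataclass
class SetEvaluation:
    """End-to-end result for one exercise set."""

    counts: ConfusionCounts
    accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    n_predicted_segments: int
    n_dropped_segments: int
    empty: bool = False


def evaluate_biofeedback(
    sig: DerivedSignals,
    manual: SegmentAnnotation,
    template,
    params,
    model,
    positive_label: str = "correct",
    fixed_length: int = 256,
) -> SetEvaluation:
    """Run the full pipeline on one set: automatic segmentation, feature
    extraction, classification, then scoring against the ground-truth
    labels of the overlapping manual repetitions.

    Only repetitions the segmenter finds are classified (missed ones do not
    enter the counts); an empty segmentation yields zero counts flagged
    ``empty``.
    """
    from .features import extract_features
    from .segmentation import segment_session

    predicted = segment_session(sig, template, params)
    usable = [r for r in predicted if r.n_samples >= 4]
    if not usable:
        return SetEvaluation(
            counts=ConfusionCounts(), accuracy=None, sensitivity=None,
            specificity=None, n_predicted_segments=0, n_dropped_segments=0,
            empty=True,
        )
    pairs, dropped = align_segments_to_labels(
        SegmentAnnotation(reps=usable), manual
    )
    if not pairs:
        return SetEvaluation(
            counts=ConfusionCounts(), accuracy=None, sensitivity=None,
            specificity=None, n_predicted_segments=len(usable),
            n_dropped_segments=dropped, empty=True,
        )
    X = np.stack([extract_features(sig, p.predicted, fixed_length) for p in pairs])
    y_pred = model.predict(X)
    y_true = np.array([p.label for p in pairs])
    pos = positive_label
    counts = ConfusionCounts(
        tp=int(np.sum((y_true == pos) & (y_pred == pos))),
        tn=int(np.sum((y_true != pos) & (y_pred != pos))),
        fp=int(np.sum((y_true != pos) & (y_pred == pos))),
        fn=int(np.sum((y_true == pos) & (y_pred != pos))),
    )
    accuracy, sensitivity, specificity = classification_metrics(counts)
    return SetEvaluation(
        counts=counts, accuracy=accuracy, sensitivity=sensitivity,
        specificity=specificity, n_predicted_segments=len(usable),
        n_dropped_segments=dropped,
    )


def summarize_cohort(values: Sequence[float], unit: str = "set") -> CohortSummary:
    """Mean and 95% t-interval of per-unit percentages, clipped to [0, 100].

    A single value yields a degenerate interval equal to the point.
    """
    values = [float(v) for v in values]
    if not values:
        raise ValidationError("cannot summarize an empty list")
    n = len(values)
    mean = float(np.mean(values))
    if n == 1 or float(np.std(values, ddof=0)) == 0.0:
        lo = hi = mean
    else:
        sd = float(np.std(values, ddof=1))
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        lo, hi = mean - half, mean + half
    lo = float(np.clip(lo, 0.0, 100.0))
    hi = float(np.clip(hi, 0.0, 100.0))
    return CohortSummary(
        values=values, unit=unit, mean=mean,
        ci_lower=lo, ci_upper=hi, band=accuracy_band(mean),
    )
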