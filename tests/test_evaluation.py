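import numpy as np
import pytest

from imurehab.evaluation import (
    ConfusionCounts,
    ToleranceConfig,
    accuracy_band,
    align_segments_to_labels,
    classification_metrics,
    match_boundaries,
    segmentation_metrics,
    summarize_cohort,
)
from imurehab.io import Repetition, SegmentAnnotation, ValidationError
from oracles import brute_force_match

FS = 100.0  # round sample rate keeps hand-built cases exact
TOL = ToleranceConfig(t_before=0.5, t_after=0.25, sample_rate=FS)


def _ann(bounds, labels=None):
    reps = []
    for i, (s, e) in enumerate(bounds):
        lab = labels[i] if labels else None
        reps.append(Repetition(int(s), int(e), lab))
    return SegmentAnnotation(reps=reps)


class TestClassificationMetrics:
    def test_perfect_counts(self):
        acc, sens, spec = classification_metrics(ConfusionCounts(tp=10, tn=10))
        assert (acc, sens, spec) == (100.0, 100.0, 100.0)

    def test_all_positive_test_set_has_no_specificity(self):
        acc, sens, spec = classification_metrics(ConfusionCounts(tp=148))
        assert acc == 100.0 and sens == 100.0
        assert spec is None

    def test_hand_computed_mixed_counts(self):
        acc, sens, spec = classification_metrics(
            ConfusionCounts(tp=3, tn=2, fp=1, fn=4)
        )
        assert acc == pytest.approx(50.0, abs=1e-9)
        assert sens == pytest.approx(100 * 3 / 7, abs=1e-9)
        assert spec == pytest.approx(100 * 2 / 3, abs=1e-9)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValidationError):
            classification_metrics(ConfusionCounts())

    def test_scale_free_in_counts(self):
        c1 = ConfusionCounts(tp=3, tn=2, fp=1, fn=4)
        c5 = ConfusionCounts(tp=15, tn=10, fp=5, fn=20)
        assert classification_metrics(c1) == classification_metrics(c5)


class TestSegmentationMetrics:
    def test_perfect_counts(self):
        assert segmentation_metrics(ConfusionCounts(tp=10)) == (100.0, 100.0, 100.0)

    def test_hand_computed_counts(self):
        p, r, a = segmentation_metrics(ConfusionCounts(tp=9, fp=1, fn=1))
        assert p == pytest.approx(90.0, abs=1e-9)
        assert r == pytest.approx(90.0, abs=1e-9)
        assert a == pytest.approx(100 * 9 / 11, abs=1e-9)

    def test_false_positives_only(self):
        p, r, a = segmentation_metrics(ConfusionCounts(fp=5))
        assert p == 0.0 and a == 0.0 and r is None

    def test_scale_free_in_counts(self):
        assert segmentation_metrics(
            ConfusionCounts(tp=9, fp=1, fn=1)
        ) == segmentation_metrics(ConfusionCounts(tp=27, fp=3, fn=3))


class TestBoundaryMatcher:
    def test_exact_prediction_gives_two_tp_per_rep(self):
        manual = _ann([(100, 400), (600, 900), (1100, 1400)])
        counts = match_boundaries(manual, manual, TOL)
        assert counts == ConfusionCounts(tp=6)

    def test_start_inside_asymmetric_window_is_tp(self):
        manual = _ann([(600, 900)])
        early = _ann([(600 - 40, 900)])  # 0.4 s early, inside the 0.5 s slack
        assert match_boundaries(early, manual, TOL).tp == 2
        late = _ann([(600 + 30, 900)])  # 0.3 s late, outside the 0.25 s slack
        assert match_boundaries(late, manual, TOL) == ConfusionCounts(tp=1, fp=1, fn=1)

    def test_escape_clause_depends_on_previous_rep_end(self):
        # predicted start 0.7 s early; previous rep ends 1.0 s before manual
        manual = _ann([(100, 500), (600, 900)])
        pred_ok = _ann([(100, 500), (600 - 70, 900)])
        counts = match_boundaries(pred_ok, manual, TOL)
        assert counts.tp == 4 and counts.fp == 0
        # same offset but previous rep ends only 0.5 s before the manual start
        manual_tight = _ann([(100, 550), (600, 900)])
        pred_bad = _ann([(100, 525), (600 - 70, 900)])
        counts = match_boundaries(pred_bad, manual_tight, TOL)
        assert counts.fp == 1 and counts.fn == 1

    def test_end_escape_clause_mirrors_start(self):
        manual = _ann([(100, 400), (700, 1000)])
        # predicted end 0.8 s late but still before the next rep start
        pred = _ann([(100, 480), (700, 1000)])
        assert match_boundaries(pred, manual, TOL).tp == 4
        # crossing into the next repetition start is not acceptable
        pred_cross = _ann([(100, 710), (720, 1000)])
        assert match_boundaries(pred_cross, manual, TOL).fp >= 1

    def test_spurious_and_missed_reps_counted(self):
        manual = _ann([(100, 400), (700, 1000)])
        pred = _ann([(100, 400)])
        counts = match_boundaries(pred, manual, TOL)
        assert counts == ConfusionCounts(tp=2, fn=2)

    def test_agrees_with_exhaustive_assignment_on_small_sessions(self):
        rng = np.random.default_rng(23)
        for trial in range(60):
            n_reps = rng.integers(1, 6)
            bounds, cursor = [], 0
            for _ in range(n_reps):
                cursor += rng.integers(80, 300)  # >= 0.8 s rest
                start = cursor
                cursor += rng.integers(100, 400)  # >= 1 s repetition
                bounds.append((start, cursor))
            manual = _ann(bounds)
            pred_bounds = []
            for s, e in bounds:
                if rng.random() < 0.15:
                    continue  # missed repetition
                js = int(rng.normal(0, 40))
                je = int(rng.normal(0, 40))
                ps, pe = s + js, max(e + je, s + js + 10)
                pred_bounds.append((max(ps, 0), pe))
            pred_bounds.sort()
            merged = []
            for s, e in pred_bounds:  # keep predictions non-overlapping
                if merged and s < merged[-1][1]:
                    s = merged[-1][1] + 1
                    if s >= e:
                        continue
                merged.append((s, e))
            if not merged:
                continue
            pred = _ann(merged)
            got = match_boundaries(pred, manual, TOL)
            expected = brute_force_match(pred, manual, TOL)
            assert got == expected, f"trial {trial}"

    def test_widening_tolerance_never_loses_tp(self):
        rng = np.random.default_rng(31)
        manual = _ann([(100, 400), (600, 900), (1200, 1500)])
        pred = _ann([(80, 430), (640, 980), (1190, 1460)])
        last_tp = -1
        for slack in (0.0, 0.1, 0.25, 0.5, 1.0):
            tol = ToleranceConfig(t_before=slack, t_after=slack / 2, sample_rate=FS)
            tp = match_boundaries(pred, manual, tol).tp
            assert tp >= last_tp
            last_tp = tp


class TestAlignment:
    def test_identity_pairing(self):
        manual = _ann([(0, 100), (200, 300)], ["correct", "sub_optimal"])
        pairs, dropped = align_segments_to_labels(_ann([(0, 100), (200, 300)]), manual)
        assert dropped == 0
        assert [p.label for p in pairs] == ["correct", "sub_optimal"]

    def test_majority_overlap_wins(self):
        manual = _ann([(0, 60), (60, 100)], ["correct", "sub_optimal"])
        pairs, _ = align_segments_to_labels(_ann([(0, 100)]), manual)
        assert len(pairs) == 1 and pairs[0].label == "correct"

    def test_spurious_rest_segment_dropped_and_counted(self):
        manual = _ann([(0, 100)], ["correct"])
        pairs, dropped = align_segments_to_labels(
            _ann([(0, 100), (500, 600)]), manual
        )
        assert len(pairs) == 1 and dropped == 1

    def test_each_manual_rep_pairs_at_most_once(self):
        manual = _ann([(0, 100)], ["correct"])
        pairs, dropped = align_segments_to_labels(
            _ann([(0, 50), (50, 100)]), manual
        )
        assert len(pairs) == 1 and dropped == 1


class TestCohortSummary:
    def test_all_perfect_values(self):
        s = summarize_cohort([100.0] * 10)
        assert (s.mean, s.ci_lower, s.ci_upper) == (100.0, 100.0, 100.0)
        assert s.band == "excellent"

    def test_band_assignment_from_mean(self):
        assert summarize_cohort([58.49]).band == "poor"
        assert summarize_cohort([66.01]).band == "moderate"

    def test_two_value_interval_is_clipped(self):
        s = summarize_cohort([80.0, 100.0])
        assert s.mean == 90.0
        # t(0.975, df=1) = 12.706: the raw interval spills far outside [0,100]
        assert s.ci_lower == 0.0 and s.ci_upper == 100.0

    def test_t_interval_hand_computation(self):
        values = [70.0, 75.0, 80.0]
        s = summarize_cohort(values)
        sd = np.std(values, ddof=1)
        half = 4.302652729911275 * sd / np.sqrt(3)  # t(0.975, df=2)
        assert s.ci_lower == pytest.approx(75.0 - half)
        assert s.ci_upper == pytest.approx(75.0 + half)

    def test_single_value_interval_degenerates_to_point(self):
        s = summarize_cohort([73.2])
        assert (s.ci_lower, s.mean, s.ci_upper) == (73.2, 73.2, 73.2)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            summarize_cohort([])

    def test_bands_partition_the_full_scale(self):
        for v in np.linspace(0, 100, 2001):
            band = accuracy_band(float(v))
            assert band in ("excellent", "good", "moderate", "poor")
        assert accuracy_band(59.9) == "poor"
        assert accuracy_band(60.0) == "moderate"
        assert accuracy_band(80.0) == "good"
        assert accuracy_band(90.0) == "excellent"
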