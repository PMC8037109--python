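import numpy as np
import pytest

from imurehab.io import DerivedSignals
from imurehab.segmentation import (
    ConfigurationError,
    ExerciseTemplate,
    SegmenterParams,
    build_template,
    cluster_rest_periods,
    detect_rest_periods,
    match_template,
    segment_session,
)

FS = 102.4


def _signals_from_gyro_y(gy, fs=FS):
    n = len(gy)
    z = np.zeros(n)
    return DerivedSignals(
        accel_x=z, accel_y=z, accel_z=np.ones(n),
        gyro_x=z, gyro_y=np.asarray(gy, dtype=float), gyro_z=z,
        magnitude=np.ones(n), pitch=z, roll=z, sample_rate=fs,
    )


class TestRestDetection:
    def test_constant_zero_gyro_is_one_full_interval(self):
        sig = _signals_from_gyro_y(np.zeros(500))
        assert detect_rest_periods(sig, SegmenterParams()) == [(0, 500)]

    def test_noise_free_session_has_leading_inter_and_trailing_rest(
        self, noise_free_signals
    ):
        sig, ann = noise_free_signals
        intervals = detect_rest_periods(sig, SegmenterParams())
        assert len(intervals) == len(ann) + 1  # 16 for 15 reps
        for (s0, e0), (s1, e1) in zip(intervals, intervals[1:]):
            assert e0 <= s1

    def test_zero_threshold_on_noisy_signal_is_empty(self):
        rng = np.random.default_rng(0)
        sig = _signals_from_gyro_y(rng.normal(0, 5, 400))
        params = SegmenterParams(rest_threshold=0.0)
        assert detect_rest_periods(sig, params) == []


class TestRestClustering:
    def test_single_interval_midpoint(self):
        pts = cluster_rest_periods([(100, 200)], SegmenterParams(), FS)
        assert pts == [150]

    def test_close_intervals_merge(self):
        # 0.1 s apart with a 0.5 s merge gap -> one reference point
        params = SegmenterParams(min_rest_gap=0.5)
        gap = int(0.1 * FS)
        a, b = (0, 100), (100 + gap, 200 + gap)
        pts = cluster_rest_periods([a, b], params, FS)
        assert len(pts) == 1
        assert pts[0] == (a[0] + b[1]) // 2

    def test_well_separated_intervals_keep_one_point_each(self):
        sep = int(5 * FS)
        intervals = [(i * sep, i * sep + 50) for i in range(4)]
        pts = cluster_rest_periods(intervals, SegmenterParams(), FS)
        assert len(pts) == 4
        assert pts == sorted(pts)


class TestTemplate:
    def _pulse(self, n=200, amp=50.0):
        u = np.arange(n) / n
        return amp * np.sin(2 * np.pi * u)

    def test_single_rep_template_is_that_rep_normalized(self):
        params = SegmenterParams()
        rep = self._pulse()
        t = build_template([rep], params)
        expected = np.interp(
            np.linspace(0, 1, params.template_length),
            np.linspace(0, 1, len(rep)), rep,
        )
        expected /= np.sqrt(np.sum(expected**2))
        assert np.allclose(t.vector, expected)
        assert np.sum(t.vector**2) == pytest.approx(1.0)

    def test_duplicated_reps_give_same_template_as_one(self):
        params = SegmenterParams()
        rep = self._pulse()
        t1 = build_template([rep], params)
        t2 = build_template([rep, rep.copy()], params)
        assert np.allclose(t1.vector, t2.vector)

    def test_averaging_denoises(self):
        params = SegmenterParams()
        rng = np.random.default_rng(3)
        clean = self._pulse(256)
        noisy = [clean + rng.normal(0, 10, len(clean)) for _ in range(50)]
        t = build_template(noisy, params)
        clean_t = build_template([clean], params)
        corr = np.corrcoef(t.vector, clean_t.vector)[0, 1]
        assert corr > 0.99

    def test_empty_training_set_rejected(self):
        with pytest.raises(ConfigurationError):
            build_template([], SegmenterParams())

    def test_template_round_trips_through_json(self, tmp_path, hs_template):
        path = tmp_path / "t.json"
        hs_template.save(path)
        back = ExerciseTemplate.load(path)
        assert back.exercise == hs_template.exercise
        assert np.allclose(back.vector, hs_template.vector)


class TestMatching:
    def test_self_match_scores_one(self, hs_template):
        params = SegmenterParams()
        score, accepted = match_template(hs_template.vector, hs_template, params)
        assert score == pytest.approx(1.0)
        assert accepted

    def test_anti_correlated_candidate_rejected(self, hs_template):
        params = SegmenterParams()
        score, accepted = match_template(-hs_template.vector, hs_template, params)
        assert score == pytest.approx(-1.0)
        assert not accepted

    def test_pure_noise_always_rejected(self, hs_template):
        params = SegmenterParams()
        rng = np.random.default_rng(17)
        scores = [
            match_template(rng.normal(0, 30, 300), hs_template, params)[0]
            for _ in range(100)
        ]
        assert max(scores) < params.match_threshold

    def test_zero_energy_candidate_scores_zero_rejected(self, hs_template):
        score, accepted = match_template(
            np.zeros(50), hs_template, SegmenterParams()
        )
        assert score == 0.0 and not accepted


class TestSegmentSession:
    def test_noise_free_session_recovers_all_boundaries(
        self, noise_free_signals, hs_template
    ):
        sig, ann = noise_free_signals
        params = SegmenterParams()
        pred = segment_session(sig, hs_template, params)
        assert len(pred) == len(ann)
        tol = 0.25 * sig.sample_rate
        assert np.all(np.abs(pred.starts() - ann.starts()) <= tol)
        assert np.all(np.abs(pred.ends() - ann.ends()) <= tol)

    def test_pure_rest_yields_empty_annotation(self, hs_template):
        sig = _signals_from_gyro_y(np.zeros(3000))
        assert len(segment_session(sig, hs_template, SegmenterParams())) == 0

    def test_noise_burst_repetition_is_rejected(
        self, noise_free_signals, hs_template
    ):
        sig, ann = noise_free_signals
        rng = np.random.default_rng(5)
        victim = ann.reps[7]
        sig.gyro_y[victim.start:victim.end] = rng.normal(
            0, 40, victim.n_samples
        )
        pred = segment_session(sig, hs_template, SegmenterParams())
        assert len(pred) == len(ann) - 1

    def test_raising_match_threshold_never_adds_segments(
        self, noise_free_signals, hs_template
    ):
        sig, _ = noise_free_signals
        counts = []
        for thr in (0.0, 0.3, 0.6, 0.9, 0.99):
            params = SegmenterParams(match_threshold=thr)
            counts.append(len(segment_session(sig, hs_template, params)))
        assert counts == sorted(counts, reverse=True)

    def test_segments_sorted_within_signal_and_disjoint(
        self, noise_free_signals, hs_template
    ):
        sig, _ = noise_free_signals
        pred = segment_session(sig, hs_template, SegmenterParams())
        assert pred.reps[0].start >= 0 and pred.reps[-1].end <= sig.n_samples
        for a, b in zip(pred.reps, pred.reps[1:]):
            assert a.end <= b.start
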