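"""Four-phase study orchestration on synthetic cohorts.

Phase 1 trains the five classifier families per exercise on the synthetic
training cohort and selects the best by leave-one-subject-out accuracy.
Phase 2 evaluates the selected classifiers on manually (ground-truth)
segmented healthy and clinical test cohorts.  Phase 3 evaluates the
template-matching segmenter against ground-truth boundaries under the
asymmetric temporal tolerance.  Phase 4 evaluates the combined system —
automatic segmentation feeding classification.  The bundle also contains a
data manifest with class-balance percentages and a healthy-to-clinical
degradation summary.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import classification as clf
from . import evaluation as ev
from . import features as ft
from . import segmentation as seg
from .io import EXERCISES, derive_signals
from .synth import (
    CohortConfig,
    SessionRecord,
    clinical_preset,
    generate_cohort,
    healthy_preset,
    training_preset,
)

REPORT_FILES = (
    "losocv_best.csv",
    "losocv_all.csv",
    "manual_classification.csv",
    "segmentation.csv",
    "biofeedback.csv",
    "data_manifest.csv",
    "degradation.csv",
)


@dataclass
class ExperimentConfig:
    """Everything a study run depends on; outputs are a pure function of it."""

    training: CohortConfig
    healthy: CohortConfig
    clinical: CohortConfig
    segmenter: seg.SegmenterParams = field(default_factory=seg.SegmenterParams)
    tolerance: ev.ToleranceConfig = field(default_factory=ev.ToleranceConfig)
    algorithms: tuple[str, ...] = clf.ALGORITHMS
    exercises: tuple[str, ...] = EXERCISES
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0, n_subjects: int = 10) -> "ExperimentConfig":
        # disjoint seeds per cohort, all derived from the master seed
        return cls(
            training=training_preset(n_subjects=n_subjects, seed=seed),
            healthy=healthy_preset(n_subjects=n_subjects, seed=seed + 101),
            clinical=clinical_preset(n_subjects=n_subjects, seed=seed + 202),
            seed=seed,
        )

    def content_hash(self) -> str:
        blob = json.dumps(
            {
                "training": vars(self.training),
                "healthy": vars(self.healthy),
                "clinical": vars(self.clinical),
                "segmenter": vars(self.segmenter) | {},
                "tolerance": {
                    "t_before": self.tolerance.t_before,
                    "t_after": self.tolerance.t_after,
                    "sample_rate": self.tolerance.sample_rate,
                },
                "algorithms": list(self.algorithms),
                "exercises": list(self.exercises),
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """In-memory result bundle of :func:`run_study`."""

    config: ExperimentConfig
    losocv_best: pd.DataFrame
    losocv_all: pd.DataFrame
    manual_classification: pd.DataFrame
    segmentation: pd.DataFrame
    biofeedback: pd.DataFrame
    data_manifest: pd.DataFrame
    degradation: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "losocv_best.csv": self.losocv_best,
            "losocv_all.csv": self.losocv_all,
            "manual_classification.csv": self.manual_classification,
            "segmentation.csv": self.segmentation,
            "biofeedback.csv": self.biofeedback,
            "data_manifest.csv": self.data_manifest,
            "degradation.csv": self.degradation,
        }

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(out_dir / name, index=False, float_format="%.6f")
        meta = {
            "config_hash": self.config.content_hash(),
            "seed": self.config.seed,
            "algorithms": list(self.config.algorithms),
            "exercises": list(self.config.exercises),
        }
        with open(out_dir / "run_metadata.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _fmt(v: Optional[float]) -> float:
    return float("nan") if v is None else float(v)


def _training_datasets(
    sessions: Sequence[SessionRecord], exercises: Sequence[str]
) -> dict[str, clf.LabelledDataset]:
    """Ground-truth-segmented feature datasets per exercise."""
    out = {}
    for exercise in exercises:
        X, y, subj = [], [], []
        for s in sessions:
            if s.exercise != exercise:
                continue
            sig = derive_signals(s.recording)
            for rep in s.annotation:
                X.append(ft.extract_features(sig, rep))
                y.append(rep.label)
                subj.append(s.subject_id)
        out[exercise] = clf.LabelledDataset(
            X=np.stack(X), y=np.array(y), subjects=np.array(subj), exercise=exercise
        )
    return out


def _summary_row(cohort, exercise, metric, summary: ev.CohortSummary) -> dict:
    return {
        "cohort": cohort, "exercise": exercise, "metric": metric,
        "mean": summary.mean, "ci_lower": summary.ci_lower,
        "ci_upper": summary.ci_upper, "band": summary.band,
        "n_units": len(summary.values),
    }


def run_study(config: ExperimentConfig, out_dir: Optional[str | Path] = None) -> StudyReport:
    """Execute the four study phases and return (optionally write) the bundle."""
    rng_seed = int(
        np.random.SeedSequence([config.seed, 9001]).generate_state(1)[0] % (2**31)
    )

    training = generate_cohort(config.training, "training", config.exercises, "T")
    healthy = generate_cohort(config.healthy, "healthy", config.exercises, "H")
    clinical = generate_cohort(config.clinical, "clinical", config.exercises, "C")
    cohorts = {"healthy": healthy, "clinical": clinical}

    # ---- phase 1: LOSOCV + best-algorithm selection -----------------------
    datasets = _training_datasets(training, config.exercises)
    losocv_rows, best_rows = [], []
    best_models: dict[str, object] = {}
    for exercise in config.exercises:
        results = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for algorithm in config.algorithms:
                results.append(clf.losocv(datasets[exercise], algorithm, seed=rng_seed))
        for r in results:
            losocv_rows.append({
                "exercise": exercise, "algorithm": r.algorithm,
                "accuracy": r.accuracy, "sensitivity": _fmt(r.sensitivity),
                "specificity": _fmt(r.specificity),
                "tp": r.counts.tp, "fp": r.counts.fp,
                "tn": r.counts.tn, "fn": r.counts.fn,
            })
        best = clf.select_best_algorithm(results)
        best_result = next(r for r in results if r.algorithm == best)
        best_rows.append({
            "exercise": exercise, "algorithm": best,
            "accuracy": best_result.accuracy,
            "sensitivity": _fmt(best_result.sensitivity),
            "specificity": _fmt(best_result.specificity),
        })
        best_models[exercise] = clf.train_classifier(
            datasets[exercise], best, seed=rng_seed
        )
    losocv_all = pd.DataFrame(losocv_rows)
    losocv_best = pd.DataFrame(best_rows)

    # ---- templates from training ground truth -----------------------------
    templates = {}
    for exercise in config.exercises:
        reps = []
        for s in training:
            if s.exercise != exercise:
                continue
            sig = derive_signals(s.recording)
            reps.extend(sig.gyro_y[r.start:r.end] for r in s.annotation)
        templates[exercise] = seg.build_template(reps, config.segmenter, exercise)

    # per-set caches reused across phases
    derived = {id(s): derive_signals(s.recording) for c in cohorts.values() for s in c}

    # ---- phase 2: classification on manual segments -----------------------
    manual_rows = []
    for cohort_name, sessions in cohorts.items():
        for exercise in config.exercises:
            accs, senss, specs = [], [], []
            for s in sessions:
                if s.exercise != exercise:
                    continue
                sig = derived[id(s)]
                X = ft.feature_matrix(sig, s.annotation)
                y_pred = best_models[exercise].predict(X)
                y_true = np.array(s.annotation.labels())
                pos = clf.POSITIVE_LABEL
                counts = ev.ConfusionCounts(
                    tp=int(np.sum((y_true == pos) & (y_pred == pos))),
                    tn=int(np.sum((y_true != pos) & (y_pred != pos))),
                    fp=int(np.sum((y_true != pos) & (y_pred == pos))),
                    fn=int(np.sum((y_true == pos) & (y_pred != pos))),
                )
                a, se, sp = ev.classification_metrics(counts)
                accs.append(a)
                if se is not None:
                    senss.append(se)
                if sp is not None:
                    specs.append(sp)
            for metric, vals in (("accuracy", accs), ("sensitivity", senss),
                                 ("specificity", specs)):
                if vals:
                    manual_rows.append(_summary_row(
                        cohort_name, exercise, metric, ev.summarize_cohort(vals)))
    manual_classification = pd.DataFrame(manual_rows)

    # ---- phase 3: segmentation under temporal tolerance -------------------
    seg_rows = []
    seg_acc_means: dict[tuple[str, str], float] = {}
    for cohort_name, sessions in cohorts.items():
        for exercise in config.exercises:
            precs, recs, accs = [], [], []
            for s in sessions:
                if s.exercise != exercise:
                    continue
                predicted = seg.segment_session(
                    derived[id(s)], templates[exercise], config.segmenter
                )
                counts = ev.match_boundaries(predicted, s.annotation, config.tolerance)
                p, r, a = ev.segmentation_metrics(counts)
                if p is not None:
                    precs.append(p)
                if r is not None:
                    recs.append(r)
                accs.append(a)
            for metric, vals in (("precision", precs), ("recall", recs),
                                 ("accuracy", accs)):
                if vals:
                    summary = ev.summarize_cohort(vals)
                    seg_rows.append(_summary_row(cohort_name, exercise, metric, summary))
                    if metric == "accuracy":
                        seg_acc_means[(cohort_name, exercise)] = summary.mean
    segmentation = pd.DataFrame(seg_rows)

    # ---- phase 4: combined biofeedback evaluation -------------------------
    bio_rows = []
    bio_acc_means: dict[tuple[str, str], float] = {}
    for cohort_name, sessions in cohorts.items():
        for exercise in config.exercises:
            accs, senss, specs, flagged = [], [], [], 0
            for s in sessions:
                if s.exercise != exercise:
                    continue
                result = ev.evaluate_biofeedback(
                    derived[id(s)], s.annotation, templates[exercise],
                    config.segmenter, best_models[exercise],
                )
                if result.empty:
                    flagged += 1
                    continue
                accs.append(result.accuracy)
                if result.sensitivity is not None:
                    senss.append(result.sensitivity)
                if result.specificity is not None:
                    specs.append(result.specificity)
            for metric, vals in (("accuracy", accs), ("sensitivity", senss),
                                 ("specificity", specs)):
                if vals:
                    summary = ev.summarize_cohort(vals)
                    bio_rows.append(_summary_row(cohort_name, exercise, metric, summary))
                    if metric == "accuracy":
                        bio_acc_means[(cohort_name, exercise)] = summary.mean
    biofeedback = pd.DataFrame(bio_rows)

    # ---- manifest with class balance --------------------------------------
    manifest_rows = []
    for cohort_name, sessions in (("training", training), *cohorts.items()):
        for exercise in config.exercises:
            subset = [s for s in sessions if s.exercise == exercise]
            total = sum(len(s.annotation) for s in subset)
            correct = sum(
                1 for s in subset for lab in s.annotation.labels() if lab == "correct"
            )
            manifest_rows.append({
                "cohort": cohort_name, "exercise": exercise,
                "participants": len({s.subject_id for s in subset}),
                "sets": len(subset),
                "total_reps": total,
                "correct_reps": correct,
                "sub_optimal_reps": total - correct,
                "correct_pct": class_balance_percent(correct, total),
            })
    data_manifest = pd.DataFrame(manifest_rows)

    # ---- degradation summary ----------------------------------------------
    deg_rows = []
    for stage, means in (("segmentation", seg_acc_means), ("biofeedback", bio_acc_means)):
        diffs = []
        for exercise in config.exercises:
            h = means.get(("healthy", exercise))
            c = means.get(("clinical", exercise))
            if h is None or c is None:
                continue
            diffs.append(h - c)
            deg_rows.append({
                "stage": stage, "exercise": exercise,
                "healthy_mean": h, "clinical_mean": c, "reduction": h - c,
            })
        if diffs:
            deg_rows.append({
                "stage": stage, "exercise": "MEAN",
                "healthy_mean": float("nan"), "clinical_mean": float("nan"),
                "reduction": float(np.mean(diffs)),
            })
    degradation = pd.DataFrame(deg_rows)

    report = StudyReport(
        config=config,
        losocv_best=losocv_best,
        losocv_all=losocv_all,
        manual_classification=manual_classification,
        segmentation=segmentation,
        biofeedback=biofeedback,
        data_manifest=data_manifest,
        degradation=degradation,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


# ---------------------------------------------------------------------------
# printed-table arithmetic

def round_printed(x: float, decimals: int = 2) -> float:
    """Round half-up, matching how the summary tables print values."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def table_arithmetic_check(
    table: Mapping[str, tuple[float, float]]
) -> dict:
    """Per-exercise healthy-to-clinical reductions and their mean from a
    table of (healthy_mean, clinical_mean) percentages."""
    if not table:
        raise ValueError("empty table")
    per_exercise = {ex: h - c for ex, (h, c) in table.items()}
    return {
        "per_exercise": per_exercise,
        "mean_reduction": float(np.mean(list(per_exercise.values()))),
    }


def class_balance_percent(correct: int, total: int) -> float:
    """Correct-repetition share of a (correct, total) count pair, percent,
    rounded to one decimal as composition tables print it."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * correct / total, 1)
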