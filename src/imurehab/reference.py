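"""Bundled reference summary tables for the worked-example arithmetic checks.

These are the published per-exercise evaluation summaries of the deployed
shank-worn biofeedback system this pipeline models: stage-wise mean
accuracies (percent) for the healthy and clinical test cohorts, and the
test-set composition counts.  They serve as *inputs* to
:func:`imurehab.study.table_arithmetic_check` — the package recomputes the
healthy-to-clinical degradation figures and class-balance percentages from
them; it does not use them to fit or tune anything.
"""

from __future__ import annotations

#: Mean segmentation accuracy (%) per exercise: (healthy cohort, clinical cohort).
SEGMENTATION_ACCURACY = {
    "HS": (92.24, 70.64),
    "IRQ": (92.64, 75.03),
    "SLR": (90.48, 81.50),
    "SAKE": (89.76, 77.01),
}

#: Mean combined-system classification accuracy (%) per exercise:
#: (healthy cohort, clinical cohort).
BIOFEEDBACK_ACCURACY = {
    "HS": (100.00, 98.49),
    "IRQ": (86.00, 59.90),
    "SLR": (76.47, 67.30),
    "SAKE": (100.00, 68.86),
}

#: Test-set composition: (cohort, exercise) -> (participants, sets,
#: total repetitions, correctly performed repetitions).
TEST_SET_COUNTS = {
    ("healthy", "HS"): (10, 10, 148, 148),
    ("healthy", "IRQ"): (10, 10, 150, 150),
    ("healthy", "SLR"): (10, 10, 150, 150),
    ("healthy", "SAKE"): (10, 10, 150, 150),
    ("clinical", "HS"): (10, 23, 320, 320),
    ("clinical", "IRQ"): (10, 18, 270, 203),
    ("clinical", "SLR"): (10, 21, 297, 148),
    ("clinical", "SAKE"): (11, 17, 241, 103),
}
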