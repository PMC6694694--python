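"""Bundled summary tables from a large community DR screening program.

Two small datasets ship with the package for demonstrating and validating
the evaluation statistics without any raster data:

* :func:`screening_confusion_counts` — the clinician-by-system grade
  count table from a screening campaign of 19,904 non-mydriatic fundus
  photographs of 6013 diabetic patients (rows: clinician consensus grade,
  columns: automated system output).
* :func:`lesion_group_summaries` — per-group (n, mean, SD) of the six
  lesion-quantification indices measured on high-quality photographs at
  three DR severity levels (group 1: mild+moderate NPDR, group 2: severe
  NPDR, group 3: PDR).

Both are count/summary tables, not image data; they are the canonical
inputs for :func:`fundusdr.evaluation.cohort_summary`,
:func:`fundusdr.evaluation.anova_oneway_summary` and
:func:`fundusdr.evaluation.lsd_pairwise`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import ConfusionMatrix

#: clinician reference labels (rows), in table order
REFERENCE_LABELS = [
    "No DR",
    "Mild NPDR",
    "Moderate NPDR",
    "Severe NPDR",
    "PDR",
    "PRP",
    "Other diseases",
    "Disqualification",
]

#: automated-system output labels (columns), in table order
SYSTEM_LABELS = [
    "DR0",
    "DR1",
    "DR2",
    "DR3",
    "PRP",
    "Other diseases",
    "Disqualification",
]

_SCREENING_COUNTS = [
    # DR0   DR1  DR2  DR3  PRP other disq
    [5377, 290, 782, 223, 23, 74, 2497],   # No DR
    [213, 152, 88, 5, 1, 7, 152],          # Mild NPDR
    [176, 111, 583, 129, 3, 4, 184],       # Moderate NPDR
    [0, 0, 6, 65, 0, 0, 1],                # Severe NPDR
    [0, 0, 1, 8, 0, 0, 3],                 # PDR
    [5, 5, 28, 20, 28, 0, 16],             # PRP
    [39, 10, 71, 86, 17, 1, 51],           # Other diseases
    [203, 50, 595, 391, 30, 3, 7097],      # Disqualification
]

#: reference labels counted as DR when computing prevalence
DR_REFERENCE_LABELS = ["Mild NPDR", "Moderate NPDR", "Severe NPDR", "PDR", "PRP"]


def screening_counts_frame() -> pd.DataFrame:
    """The raw clinician-by-system count table as a DataFrame."""
    return pd.DataFrame(_SCREENING_COUNTS, index=REFERENCE_LABELS, columns=SYSTEM_LABELS)


def screening_confusion_counts() -> ConfusionMatrix:
    """The count table as a square :class:`ConfusionMatrix`.

    Reference and system label sets differ (clinicians grade five DR
    stages, the system outputs DR0-DR3), so the square matrix is built on
    the union of the label lists with zero rows/columns where a label is
    unused on one side.  Row totals are what the cohort arithmetic uses.
    """
    labels = REFERENCE_LABELS + [l for l in SYSTEM_LABELS if l not in REFERENCE_LABELS]
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    ridx = {l: i for i, l in enumerate(labels)}
    for ref, row in zip(REFERENCE_LABELS, _SCREENING_COUNTS):
        for sys, c in zip(SYSTEM_LABELS, row):
            counts[ridx[ref], ridx[sys]] += c
    return ConfusionMatrix(labels, counts)


# (n, mean, sd) per group for each quantification index, groups 1..3
_LESION_GROUP_STATS = {
    "hemorrhage_total_area_px": [
        (39, 921.05, 1319.560),
        (29, 15218.59, 17031.178),
        (23, 16479.22, 15613.505),
    ],
    "hemorrhage_count": [
        (39, 3.26, 2.702),
        (29, 26.62, 17.551),
        (23, 11.35, 9.384),
    ],
    "hemorrhage_max_area_px": [
        (39, 636.03, 1021.743),
        (29, 3595.55, 3211.929),
        (23, 7133.70, 7550.703),
    ],
    "exudate_total_area_px": [
        (39, 1496.46, 2699.786),
        (29, 6589.90, 10347.651),
        (23, 15062.87, 18862.476),
    ],
    "exudate_count": [
        (39, 6.00, 10.665),
        (29, 20.66, 26.203),
        (23, 11.96, 14.729),
    ],
    "exudate_max_area_px": [
        (39, 578.87, 1363.809),
        (29, 1622.69, 3186.810),
        (23, 7084.78, 8306.680),
    ],
}

GROUP_LABELS = ["group1", "group2", "group3"]


def lesion_group_summaries() -> dict[str, list[tuple[int, float, float]]]:
    """(n, mean, sample SD) triples per index for the three severity groups."""
    return {k: list(v) for k, v in _LESION_GROUP_STATS.items()}
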