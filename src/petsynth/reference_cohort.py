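"""Reference reader-study detection counts for validating the aggregation.

Summary of a published 50-patient clinical reader study of synthetic
full-time whole-body FDG-PET: per-organ, per-PERCIST-stratum counts of
reference lesions detected / missed in the synthetic images, plus the
patient-level outcome (33 lesion-positive patients of 50, 26 detected, no
false positives among the 17 lesion-free patients).

These counts are used as fixture input to :func:`petsynth.lesions.detection_report`:
expanding them to one row per lesion and aggregating must reproduce the
published detection rates (e.g. 0.78 for all PERCIST-measurable lesions,
0.22 for non-measurable ones, 65% over all 298 lesions, 79% patient
sensitivity, 100% specificity).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["LESION_COUNTS", "PATIENT_COUNTS", "reference_lesion_table", "reference_patient_table"]

#: (organ, stratum) -> (detected, missed) reference-lesion counts.
LESION_COUNTS: dict[tuple[str, str], tuple[int, int]] = {
    ("bones", "percist"): (119, 23),
    ("bones", "non_percist"): (5, 7),
    ("liver", "percist"): (5, 1),
    ("liver", "non_percist"): (0, 3),
    ("lung", "percist"): (21, 3),
    ("lung", "non_percist"): (3, 10),
    ("lymph nodes", "percist"): (27, 16),
    ("lymph nodes", "non_percist"): (6, 27),
    ("other", "percist"): (6, 8),
    ("other", "non_percist"): (1, 7),
}

#: Patient-level study outcome.
PATIENT_COUNTS = {
    "n_patients": 50,
    "n_positive": 33,
    "n_positive_detected": 26,
    "n_negative": 17,
    "n_false_positive": 0,
}


def reference_lesion_table() -> pd.DataFrame:
    """Expand the counts to one row per lesion for ``detection_report``.

    Lesions are distributed over nominal patient ids (the true per-patient
    composition is not published, so patient- and organ-level aggregates of
    this table are nominal; lesion-level rates are exact).
    """
    rows = []
    lesion_id = 0
    for (organ, stratum), (n_det, n_miss) in sorted(LESION_COUNTS.items()):
        for detected, count in ((True, n_det), (False, n_miss)):
            for _ in range(count):
                lesion_id += 1
                rows.append(
                    {
                        "patient": f"P{lesion_id % PATIENT_COUNTS['n_positive']:02d}",
                        "lesion_id": lesion_id,
                        "organ": organ,
                        "percist": stratum == "percist",
                        "detected": detected,
                    }
                )
    return pd.DataFrame(rows)


def reference_patient_table() -> pd.DataFrame:
    """Per-patient positivity flags reproducing sensitivity and specificity."""
    c = PATIENT_COUNTS
    rows = []
    for i in range(c["n_positive"]):
        rows.append(
            {
                "patient": f"pos{i:02d}",
                "ref_positive": True,
                "pred_positive": i < c["n_positive_detected"],
            }
        )
    for i in range(c["n_negative"]):
        rows.append(
            {
                "patient": f"neg{i:02d}",
                "ref_positive": False,
                "pred_positive": i < c["n_false_positive"],
            }
        )
    return pd.DataFrame(rows)
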