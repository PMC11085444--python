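"""Bundled reference tables from the benchtop-NMR honey screening study.

Two small tables, transcribed for validating the report arithmetic and the
dataset bookkeeping:

* :func:`load_test_set_report` — the published screening outcome of the
  33-sample blind test set: mean YPredPS from UV-PLS-DA model I, stage-1
  class, stage-2 projection class, the adulterant identified independently
  by NMR characterisation, the PLS-predicted level (mg/packet +/- SD over
  duplicates) and its percent deviation versus direct benchtop-NMR
  quantification.
* :func:`study_inventory` — adulterant identity for all 50 seized samples
  (training + test sets).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_test_set_report", "study_inventory"]

# sample, YPredPS, stage-1 class, stage-2 class, reference adulterant,
# level (mg/packet), level SD, % deviation vs benchtop-NMR quantification.
_TEST_SET_ROWS = [
    ("1", 1.08, "adulterated", "tadalafil", "tadalafil", 56.0, 6.0, 3.5),
    ("5", 1.47, "adulterated", "tadalafil", "tadalafil", 66.0, 12.0, 1.0),
    ("6", 0.84, "adulterated", "tadalafil", "tadalafil", 37.0, 1.0, -0.3),
    ("7", 0.73, "adulterated", "tadalafil", "tadalafil", 12.0, 1.0, 4.0),
    ("8", 0.20, "non-adulterated", "not-evaluated", "-", None, None, None),
    ("9", 1.36, "adulterated", "tadalafil", "tadalafil", 78.0, 1.0, -2.5),
    ("17", 0.58, "adulterated", "tadalafil", "tadalafil", 19.0, 1.0, 2.0),
    ("19", 1.22, "adulterated", "tadalafil", "tadalafil", 62.0, 2.0, -3.9),
    ("20", 1.12, "adulterated", "tadalafil", "tadalafil", 39.0, 1.0, 0.0),
    ("21", 1.11, "adulterated", "tadalafil", "tadalafil", 58.0, 6.0, -0.9),
    ("22", 0.61, "adulterated", "tadalafil", "tadalafil", 13.0, 1.0, 3.1),
    ("23", 1.25, "adulterated", "tadalafil", "tadalafil", 64.0, 1.0, -2.0),
    ("24", 1.53, "adulterated", "tadalafil", "tadalafil", 61.0, 1.0, -0.5),
    ("25", 0.75, "adulterated", "tadalafil", "tadalafil", 24.0, 2.0, -2.9),
    ("28", 0.69, "adulterated", "tadalafil", "tadalafil", 27.0, 2.0, 7.1),
    ("29", 0.89, "adulterated", "tadalafil", "tadalafil", 44.0, 3.0, 5.6),
    ("31", 0.90, "adulterated", "tadalafil", "tadalafil", 12.0, 1.0, 21.4),
    ("33", 1.10, "adulterated", "tadalafil", "tadalafil", 21.0, 2.0, 7.8),
    ("34", 0.72, "adulterated", "tadalafil", "tadalafil", 43.0, 4.0, -1.1),
    ("35", 0.90, "adulterated", "tadalafil", "tadalafil", 46.0, 4.0, -0.2),
    ("36", 0.69, "adulterated", "tadalafil", "tadalafil", 24.0, 1.0, 0.8),
    ("37", 0.91, "adulterated", "sildenafil", "tadalafil", None, None, None),
    ("38", 0.47, "borderline", "tadalafil", "tadalafil", 8.0, 2.0, 14.3),
    ("40", 1.03, "adulterated", "tadalafil", "tadalafil", 51.0, 1.0, -2.3),
    ("41", 0.73, "adulterated", "tadalafil", "tadalafil", 35.0, 1.0, 0.8),
    ("42", 0.20, "non-adulterated", "not-evaluated", "-", None, None, None),
    ("43", 1.04, "adulterated", "tadalafil", "tadalafil", 65.0, 7.0, -5.1),
    ("44", 2.21, "adulterated", "outlier", "tadalafil", None, None, None),
    ("45", 0.80, "adulterated", "tadalafil", "tadalafil", 33.0, 9.0, -2.1),
    ("46", 0.92, "adulterated", "tadalafil", "tadalafil", 66.0, 5.0, -2.2),
    ("47", 1.40, "adulterated", "tadalafil", "tadalafil", 84.0, 1.0, -2.6),
    ("49", 0.78, "adulterated", "sildenafil", "sildenafil", 78.0, 11.0, -2.1),
    ("50", 0.65, "adulterated", "sildenafil", "sildenafil", 67.0, 12.0, -9.3),
]


def load_test_set_report() -> pd.DataFrame:
    """Reference screening report of the 33-sample blind test set."""
    return pd.DataFrame(
        _TEST_SET_ROWS,
        columns=[
            "sample_id",
            "ypredps",
            "stage1",
            "stage2",
            "adulterant_ref",
            "level_mg_per_packet",
            "level_sd",
            "pct_dev",
        ],
    )


# Training-set membership and adulterant identity for the 50 seized samples.
_TRAIN_N = ["3", "27", "30", "32", "39"]
_TRAIN_T = ["10", "11", "12", "13", "14", "15", "16", "18", "26"]
_TRAIN_S = ["2", "4", "48"]
_TEST_N = ["8", "42"]
_TEST_S = ["49", "50"]
_TEST_T = (
    ["1", "5", "6", "7", "9", "17"]
    + [str(i) for i in range(19, 26)]
    + ["28", "29", "31"]
    + [str(i) for i in range(33, 39)]
    + ["40", "41"]
    + [str(i) for i in range(43, 48)]
)


def study_inventory() -> pd.DataFrame:
    """Adulterant identity and set membership for all 50 samples.

    Sample 7 contained flibanserin in addition to tadalafil; it is counted
    as a tadalafil sample, matching the study's tally of 38.
    """
    rows = []
    for sid in _TRAIN_N + _TEST_N:
        rows.append((sid, "none"))
    for sid in _TRAIN_T + _TEST_T:
        rows.append((sid, "tadalafil"))
    for sid in _TRAIN_S + _TEST_S:
        rows.append((sid, "sildenafil"))
    membership = {
        sid: "training" for sid in _TRAIN_N + _TRAIN_T + _TRAIN_S
    }
    df = pd.DataFrame(rows, columns=["sample_id", "adulterant"])
    df["set"] = df["sample_id"].map(lambda s: membership.get(s, "test"))
    return df.sort_values("sample_id", key=lambda s: s.astype(int)).reset_index(drop=True)
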