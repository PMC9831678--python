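"""Packaged 218-patient oral-cancer clinical cohort fixture.

Demographic and clinicopathological characteristics of an oral squamous
cell carcinoma cohort split by inpatient bacterial culture result (113
culture-negative, 105 culture-positive), transcribed from the published
per-level counts and group summary statistics.  Patient-level categorical
assignments are expanded deterministically from the per-group counts — any
expansion reproduces every variable-by-outcome margin exactly, which is all
the chi-square screen consumes.  Continuous variables are available only as
per-group (n, mean, SD) summaries, which the pooled-variance t-test uses
directly.
"""

from __future__ import annotations

import pandas as pd

from .clinical import ClinicalCohort, GroupSummary

#: per-variable {level: (count in culture-negative, count in culture-positive)}
CATEGORICAL_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "gender": {"male": (75, 74), "female": (38, 31)},
    "smoking": {"yes": (50, 56), "no": (63, 49)},
    "drinking": {"yes": (19, 22), "no": (94, 83)},
    "antibiotic_history": {"yes": (24, 27), "no": (89, 78)},
    "diabetes": {"yes": (9, 22), "no": (104, 83)},
    "site": {
        "tongue": (65, 43), "buccal": (21, 20), "gingival": (13, 19),
        "palate": (4, 5), "oral_floor": (8, 12), "others": (2, 6),
    },
    "appearance": {"exogenous": (54, 52), "ulcer": (48, 45),
                   "infiltrating": (11, 8)},
    "t_stage": {"T1/T2": (56, 33), "T3": (37, 20), "T4": (20, 52)},
    "n_stage": {"N0": (63, 43), "N1": (25, 22), "N2": (22, 37),
                "N3": (3, 3)},
    "lymph_node_metastasis": {"yes": (50, 62), "no": (63, 43)},
    "grade": {"high": (83, 62), "moderate": (29, 40), "poor": (1, 3)},
}

#: per-variable (n, mean, SD) for the culture-negative and -positive groups
CONTINUOUS_SUMMARIES: dict[str, GroupSummary] = {
    "age": GroupSummary(113, 52.06, 12.59, 105, 52.81, 12.44),
    "bmi": GroupSummary(113, 22.90, 2.68, 105, 22.71, 2.92),
    "white_blood_cell": GroupSummary(113, 6.50, 1.74, 105, 6.82, 2.35),
    "neutrophils": GroupSummary(113, 3.84, 1.47, 105, 4.21, 2.09),
    "lymphocyte": GroupSummary(113, 2.04, 0.76, 105, 1.92, 0.65),
    "nlr": GroupSummary(113, 2.12, 1.15, 105, 2.43, 1.53),
    "monocytes": GroupSummary(113, 0.44, 0.14, 105, 0.62, 1.15),
    "crp": GroupSummary(113, 2.76, 5.92, 105, 2.85, 4.61),
    "procalcitonin": GroupSummary(113, 0.06, 0.02, 105, 0.28, 2.18),
    "albumin": GroupSummary(113, 40.92, 3.35, 105, 41.33, 3.82),
}

GROUP_SIZES = {"negative": 113, "positive": 105}


def _expand_column(var: str, outcome: str, n: int) -> list[str]:
    """Deterministic level sequence for one culture group of one variable."""
    col = []
    idx = 0 if outcome == "negative" else 1
    for level, counts in CATEGORICAL_COUNTS[var].items():
        col.extend([level] * counts[idx])
    if len(col) != n:
        raise AssertionError(
            f"{var}/{outcome}: counts sum to {len(col)}, expected {n}")
    return col


def load_table1() -> ClinicalCohort:
    """Build the packaged cohort as a :class:`ClinicalCohort`."""
    frames = []
    for outcome, n in GROUP_SIZES.items():
        data = {"culture_result": [outcome] * n}
        for var in CATEGORICAL_COUNTS:
            data[var] = _expand_column(var, outcome, n)
        frames.append(pd.DataFrame(data))
    patients = pd.concat(frames, ignore_index=True)
    patients.insert(0, "patient_id",
                    [f"P{i + 1:03d}" for i in range(len(patients))])
    return ClinicalCohort(
        patients=patients,
        categorical_vars=list(CATEGORICAL_COUNTS),
        continuous_vars=list(CONTINUOUS_SUMMARIES),
        variable_levels={v: list(lv) for v, lv in CATEGORICAL_COUNTS.items()},
        continuous_summaries=dict(CONTINUOUS_SUMMARIES),
    )
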