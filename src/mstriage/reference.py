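"""Published summary statistics of the instrument's 198-patient validation study.

The original cohort is not deposited; what survives are its printed group
descriptives (diagnosis-group sizes, total-score / EDSS / age means and SDs,
relapse counts, per-item symptom and impact prevalences) and the derived
cut-offs.  These constants calibrate the synthetic-cohort generator and feed
the arithmetic consistency checks — they are inputs, not results computed by
this package.

Group order everywhere is RRMS, TRANSITIONING, SPMS.
"""

from __future__ import annotations

import pandas as pd

GROUPS = ("RRMS", "TRANSITIONING", "SPMS")

#: Diagnosis-group sizes (N = 198).
GROUP_N = {"RRMS": 89, "TRANSITIONING": 47, "SPMS": 62}

#: Standardized total score (with-EDSS algorithm), mean and SD per group.
TOTAL_SCORE = {
    "RRMS": (38.1, 12.5),
    "TRANSITIONING": (55.2, 11.1),
    "SPMS": (69.6, 12.0),
}

#: Age in years, mean and SD per group.
AGE = {
    "RRMS": (38.1, 11.3),
    "TRANSITIONING": (46.2, 10.7),
    "SPMS": (53.4, 10.7),
}

#: EDSS mean and SD per group; EDSS was missing for some patients, so the
#: per-group ns differ from GROUP_N.
EDSS = {
    "RRMS": (2.6, 1.0),
    "TRANSITIONING": (4.3, 1.1),
    "SPMS": (5.6, 1.4),
}
EDSS_N = {"RRMS": 81, "TRANSITIONING": 47, "SPMS": 61}

#: Years since RRMS diagnosis, mean and SD per group.
DURATION_RRMS = {
    "RRMS": (7.3, 6.3),
    "TRANSITIONING": (13.2, 8.4),
    "SPMS": (17.3, 10.1),
}

#: Patients with a relapse in the past 6 months (count / group size).
RELAPSE_6MO = {"RRMS": 30, "TRANSITIONING": 10, "SPMS": 9}

#: Pooled descriptives as printed: mean, SD.
POOLED = {
    "age": (44.8, 12.8),
    "edss": (4.0, 1.7),
    "duration_rrms": (11.8, 9.2),
}

#: Per-group item prevalence counts (numerator over the group size; EDSS
#: groups use GROUP_N).  Items whose per-group split was printed carry the
#: printed counts; the remainder (marked assumed) were chosen to match the
#: printed overall totals and the reported qualitative ordering.
ITEM_PREVALENCE_COUNTS: dict[str, tuple[int, int, int]] = {
    # symptoms                      RRMS  TRANS SPMS
    "fatigue": (50, 36, 52),  # assumed split of 138/198 overall
    "ambulatory": (31, 41, 58),
    "motor": (31, 40, 58),
    "sensory": (45, 34, 49),  # assumed split of 128/198 overall
    "coordination_balance": (28, 37, 55),
    "cognitive": (16, 21, 41),
    "bowel_bladder": (18, 27, 40),
    # impacts
    "self_care": (26, 37, 55),
    "mobility": (45, 44, 61),
    "hobbies_leisure": (59, 40, 57),  # assumed; ~2/3 of RRMS affected
    "work": (59, 39, 56),  # assumed
    "daily_activities": (59, 41, 58),  # assumed
}

#: Cut-off pairs derived in the validation study, by algorithm variant and
#: estimation method: (lower, upper) on the 0–100 scale.
DERIVED_CUTOFFS = {
    ("with_edss", "sum_squares"): (51.6, 58.9),
    ("with_edss", "youden"): (53.7, 58.9),
    ("without_edss", "sum_squares"): (46.3, 57.8),
    ("without_edss", "youden"): (46.3, 49.5),
}

#: The without-EDSS pair that the study cross-applied to the with-EDSS
#: algorithm scores.
CROSS_APPLIED_CUTOFFS = (46.3, 57.8)


def item_prevalence(group: str) -> dict[str, float]:
    """Per-item prevalence probabilities for one diagnosis group."""
    n = GROUP_N[group]
    i = GROUPS.index(group)
    return {item: counts[i] / n for item, counts in ITEM_PREVALENCE_COUNTS.items()}


def table1_frame() -> pd.DataFrame:
    """Printed group descriptives in tidy form (one row per cell)."""
    rows = []
    for char, stats, ns in (
        ("age", AGE, GROUP_N),
        ("edss", EDSS, EDSS_N),
        ("duration_rrms", DURATION_RRMS, GROUP_N),
    ):
        for g in GROUPS:
            mean, sd = stats[g]
            rows.append(
                {"characteristic": char, "group": g, "n": ns[g], "mean": mean, "sd": sd}
            )
    return pd.DataFrame(rows)


def pooled_frame() -> pd.DataFrame:
    rows = [
        {"characteristic": c, "mean": m, "sd": s} for c, (m, s) in POOLED.items()
    ]
    return pd.DataFrame(rows)
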