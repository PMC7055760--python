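"""Seeded synthetic cohorts and rater studies.

The generator emulates the statistical structure of the instrument's
validation cohort: three physician-diagnosis groups (RRMS, transitioning,
SPMS) of sizes 89/47/62 whose standardized totals follow normals truncated
to [0, 100] with the published group means and SDs, EDSS drawn per group and
clipped to the 0–10 half-point grid, ages drawn per group, a per-group
relapse probability, and per-item symptom/impact prevalences.  Two modes are
supported:

``summary_scores``
    Each record carries a precomputed total (``total_score_override``); this
    is the mode calibrated to the published score distributions and is what
    the ROC reproduction runs on.
``item_level``
    Item responses are drawn per item: presence ~ Bernoulli(prevalence),
    severity conditional on presence ~ a categorical over mild/moderate/
    severe tilted toward higher levels for transitioning and SPMS patients.
    Totals are then produced by the scoring engine, so EDSS–total
    correlation arises implicitly from group membership.

A single global seed drives everything through ``numpy.random.SeedSequence``
spawning (one child stream per group, in group order), so any group is
reproducible in isolation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator
from scipy import stats

from . import reference
from .scoring import Diagnosis, PatientRecord

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "RaterStudySpec",
    "default_cohort_spec",
    "default_rater_study_spec",
    "generate_cohort",
    "generate_rater_study",
    "load_cohort_spec",
]

#: Severity distribution over levels 1..3 given a symptom/impact is present,
#: before the group severity tilt (RRMS baseline).
BASE_SEVERITY = (0.50, 0.35, 0.15)

#: Default exponential tilt toward higher severity levels per group.
DEFAULT_SEVERITY_SHIFT = {"RRMS": 0.0, "TRANSITIONING": 0.6, "SPMS": 1.2}


class GroupSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    diagnosis: Diagnosis
    n: int
    total_score_mean: float
    total_score_sd: float
    edss_mean: float
    edss_sd: float
    age_mean: float
    age_sd: float
    relapse_prob: float
    item_prevalence: dict[str, float] = {}
    severity_shift: float = 0.0

    @field_validator("n")
    @classmethod
    def _check_n(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("group size must be positive")
        return v

    @model_validator(mode="after")
    def _check(self) -> "GroupSpec":
        for name in ("total_score_sd", "edss_sd", "age_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.relapse_prob <= 1:
            raise ValueError("relapse_prob must be a probability")
        for item, p in self.item_prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {item!r} must be in [0, 1]")
        return self


class CohortSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    groups: tuple[GroupSpec, ...]
    seed: int = 0
    mode: Literal["summary_scores", "item_level"] = "summary_scores"

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        labels = [g.diagnosis for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group diagnosis labels must be unique")
        return self


class RaterStudySpec(BaseModel):
    """A vignette-style interrater study: every rater scores every subject.

    The generating model is ``score(s, r) = true(s) + bias(r) + eps(s, r)``
    with rater bias ~ N(0, rater_bias_sd^2) and residual ~ N(0,
    residual_sd^2).  Defaults emulate the study design used to assess the
    instrument's reliability: 2 video vignettes (an RRMS-like and an
    SPMS-like mock patient) rated by 20 physicians, with noise levels whose
    implied ICC(2,1) is about 0.95.
    """

    model_config = ConfigDict(frozen=True)

    subject_true_scores: tuple[float, ...] = (40.0, 70.0)
    n_raters: int = 20
    rater_bias_sd: float = 2.5
    residual_sd: float = 4.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RaterStudySpec":
        if len(self.subject_true_scores) < 2:
            raise ValueError("need at least 2 subjects")
        if self.n_raters < 2:
            raise ValueError("need at least 2 raters")
        if self.rater_bias_sd < 0 or self.residual_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        return self

    @property
    def n_subjects(self) -> int:
        return len(self.subject_true_scores)


def default_cohort_spec(
    seed: int = 0, mode: str = "summary_scores"
) -> CohortSpec:
    """Cohort spec calibrated to the published validation-study structure."""
    groups = []
    for g in reference.GROUPS:
        groups.append(
            GroupSpec(
                diagnosis=Diagnosis(g),
                n=reference.GROUP_N[g],
                total_score_mean=reference.TOTAL_SCORE[g][0],
                total_score_sd=reference.TOTAL_SCORE[g][1],
                edss_mean=reference.EDSS[g][0],
                edss_sd=reference.EDSS[g][1],
                age_mean=reference.AGE[g][0],
                age_sd=reference.AGE[g][1],
                relapse_prob=reference.RELAPSE_6MO[g] / reference.GROUP_N[g],
                item_prevalence=reference.item_prevalence(g),
                severity_shift=DEFAULT_SEVERITY_SHIFT[g],
            )
        )
    return CohortSpec(groups=tuple(groups), seed=seed, mode=mode)


def default_rater_study_spec(seed: int = 0) -> RaterStudySpec:
    return RaterStudySpec(seed=seed)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int, lo: float, hi: float
) -> np.ndarray:
    """Draw from N(mean, sd^2) truncated (not clipped) to [lo, hi]."""
    if sd == 0:
        return np.full(n, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _severity_probs(shift: float) -> np.ndarray:
    # exponential tilt of the baseline severity distribution
    levels = np.arange(len(BASE_SEVERITY))
    p = np.asarray(BASE_SEVERITY) * np.exp(shift * levels)
    return p / p.sum()


def _generate_group(
    group: GroupSpec, mode: str, rng: np.random.Generator, start_index: int
) -> list[PatientRecord]:
    n = group.n
    ages = rng.normal(group.age_mean, group.age_sd, n)
    edss_raw = rng.normal(group.edss_mean, group.edss_sd, n)
    edss = np.clip(np.round(edss_raw * 2) / 2, 0.0, 10.0)
    relapse = rng.random(n) < group.relapse_prob

    totals = None
    responses: list[dict[str, int]] = [dict() for _ in range(n)]
    if mode == "summary_scores":
        totals = _truncated_normal(
            rng, group.total_score_mean, group.total_score_sd, n, 0.0, 100.0
        )
    else:
        sev_p = _severity_probs(group.severity_shift)
        for item, prev in group.item_prevalence.items():
            present = rng.random(n) < prev
            severities = rng.choice(
                np.arange(1, len(sev_p) + 1), size=n, p=sev_p
            )
            for i in range(n):
                responses[i][item] = int(severities[i]) if present[i] else 0
        for i in range(n):
            responses[i]["relapses"] = int(relapse[i])

    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"P{start_index + i:04d}",
                diagnosis=group.diagnosis,
                age=float(ages[i]),
                edss=float(edss[i]),
                relapse_6mo=bool(relapse[i]),
                responses=responses[i],
                total_score_override=(
                    float(totals[i]) if totals is not None else None
                ),
            )
        )
    return records


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Generate a seeded synthetic cohort (deterministic per spec)."""
    children = np.random.SeedSequence(spec.seed).spawn(len(spec.groups))
    records: list[PatientRecord] = []
    for group, child in zip(spec.groups, children):
        rng = np.random.default_rng(child)
        records.extend(_generate_group(group, spec.mode, rng, len(records)))
    return records


def generate_rater_study(spec: RaterStudySpec) -> pd.DataFrame:
    """Subjects x raters score grid under the additive rater model."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    true = np.asarray(spec.subject_true_scores, dtype=float)
    n, k = spec.n_subjects, spec.n_raters
    bias = rng.normal(0.0, spec.rater_bias_sd, k) if spec.rater_bias_sd else np.zeros(k)
    eps = (
        rng.normal(0.0, spec.residual_sd, (n, k))
        if spec.residual_sd
        else np.zeros((n, k))
    )
    values = true[:, None] + bias[None, :] + eps
    return pd.DataFrame(
        values,
        index=[f"S{i + 1}" for i in range(n)],
        columns=[f"R{j + 1}" for j in range(k)],
    )


def load_cohort_spec(path: str | Path) -> CohortSpec:
    """Load a cohort spec from YAML."""
    data = yaml.safe_load(Path(path).read_text())
    return CohortSpec.model_validate(data)
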