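"""Patient records, instrument scoring and traffic-light classification.

Scoring follows the published structure of the instrument: the raw score of
each section is the weighted sum of its item responses, the standardized
total rescales the pooled raw sum to a 0–100 ceiling, and the total is
classified against a lower/upper cut-off pair into three zones::

    total <= lower          -> GREEN_RRMS
    lower < total < upper   -> YELLOW_TRANSITIONING
    total >= upper          -> RED_SPMS

Boundary inclusion matches the instrument's rule that a score *equal or
above* the upper cut-off indicates SPMS and values *lower or equal* to the
lower cut-off indicate RRMS.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .instrument import EDSS_ITEM_ID, CutoffPair, InstrumentConfig, default_instrument

logger = logging.getLogger(__name__)

__all__ = [
    "Diagnosis",
    "Zone",
    "PatientRecord",
    "ScoredPatient",
    "score_sections",
    "standardize_total",
    "classify_zone",
    "score_record",
    "score_cohort",
    "InstrumentScorer",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_scored_csv",
]


class Diagnosis(str, enum.Enum):
    """Physician diagnosis from the case report form."""

    RRMS = "RRMS"
    TRANSITIONING = "TRANSITIONING"
    SPMS = "SPMS"


class Zone(str, enum.Enum):
    """Traffic-light zone induced by the cut-off pair."""

    GREEN_RRMS = "GREEN_RRMS"
    YELLOW_TRANSITIONING = "YELLOW_TRANSITIONING"
    RED_SPMS = "RED_SPMS"


#: Natural severity order used for ordinal encodings.
DIAGNOSIS_ORDER: dict[Diagnosis, int] = {
    Diagnosis.RRMS: 0,
    Diagnosis.TRANSITIONING: 1,
    Diagnosis.SPMS: 2,
}


class PatientRecord(BaseModel):
    """One patient's CRF entry: diagnosis label, demographics, responses.

    ``total_score_override`` carries a precomputed standardized total and is
    used when only summary scores are simulated; when present it bypasses
    item-level scoring.  ``t25fw`` (timed 25-foot walk, seconds) is accepted
    as a passthrough covariate and never scored.
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    diagnosis: Diagnosis
    age: float | None = None
    edss: float | None = None
    relapse_6mo: bool | None = None
    responses: dict[str, int] = {}
    total_score_override: float | None = None
    t25fw: float | None = None

    @field_validator("edss")
    @classmethod
    def _check_edss(cls, v: float | None) -> float | None:
        if v is None:
            return v
        if not 0 <= v <= 10 or round(v * 2) != v * 2:
            raise ValueError(f"EDSS must lie in [0, 10] in 0.5 steps, got {v}")
        return v


@dataclass(frozen=True)
class ScoredPatient:
    patient_id: str
    section_raw: dict[str, float]
    total: float
    zone: Zone
    diagnosis: Diagnosis | None = None


def _response_level(record: PatientRecord, item_id: str, config: InstrumentConfig) -> int | None:
    """Resolve the response level for one item, deriving EDSS if needed."""
    if item_id in record.responses:
        return record.responses[item_id]
    if item_id == EDSS_ITEM_ID and record.edss is not None:
        return int(round(record.edss * 2))
    return None


def score_sections(
    record: PatientRecord, config: InstrumentConfig
) -> dict[str, float]:
    """Raw score per section: the weighted sum of the item responses.

    Missing required responses raise; missing *optional* items score 0
    with a logged warning.  Under the without-EDSS variant the EDSS item
    is skipped entirely.
    """
    scored_ids = config.scored_item_ids()
    raw: dict[str, float] = {}
    for section in config.sections:
        s = 0.0
        for item in section.items:
            if item.id not in scored_ids:
                continue
            level = _response_level(record, item.id, config)
            if level is None:
                if item.optional:
                    logger.warning(
                        "patient %s: optional item %r missing, scored as 0",
                        record.patient_id,
                        item.id,
                    )
                    continue
                raise ValueError(
                    f"patient {record.patient_id!r}: missing response for "
                    f"required item {item.id!r}"
                )
            s += item.weight(level)  # raises if level out of range
        raw[section.name] = s
    unknown = set(record.responses) - {it.id for it in config.iter_items()}
    if unknown:
        raise ValueError(f"unknown item id(s) in responses: {sorted(unknown)}")
    return raw


def standardize_total(
    section_raw: Mapping[str, float], config: InstrumentConfig
) -> float:
    """Rescale pooled raw section scores to the 0–100 standardized total.

    total = score_max * (sum of section raws) / (sum of attainable maxima);
    with ``normalize_sections`` each section is first rescaled to its own
    maximum and the section fractions are averaged.
    """
    section_max = config.section_max()
    if set(section_raw) != set(section_max):
        raise ValueError(
            f"section keys {sorted(section_raw)} do not match the "
            f"configured sections {sorted(section_max)}"
        )
    total_max = sum(section_max.values())
    if total_max <= 0:
        raise ValueError("instrument has zero total attainable score")
    for name, v in section_raw.items():
        if not 0 <= v <= section_max[name] + 1e-9:
            raise ValueError(
                f"section {name!r} raw score {v} outside [0, {section_max[name]}]"
            )
    if config.normalize_sections:
        fracs = [
            section_raw[name] / m if m > 0 else 0.0
            for name, m in section_max.items()
        ]
        return config.score_max * float(np.mean(fracs))
    return config.score_max * sum(section_raw.values()) / total_max


def classify_zone(total: float, cutoffs: CutoffPair) -> Zone:
    """Traffic-light zone for a standardized total (boundaries inclusive)."""
    if total < -1e-9 or total > 100 + 1e-9:
        raise ValueError(f"total {total} outside the standardized 0–100 scale")
    if total <= cutoffs.lower:
        return Zone.GREEN_RRMS
    if total >= cutoffs.upper:
        return Zone.RED_SPMS
    return Zone.YELLOW_TRANSITIONING


def score_record(record: PatientRecord, config: InstrumentConfig) -> ScoredPatient:
    """Score one patient, honouring a precomputed summary total if present."""
    if record.total_score_override is not None:
        total = float(record.total_score_override)
        section_raw: dict[str, float] = {}
    else:
        section_raw = score_sections(record, config)
        total = standardize_total(section_raw, config)
    return ScoredPatient(
        patient_id=record.patient_id,
        section_raw=section_raw,
        total=total,
        zone=classify_zone(total, config.cutoffs),
        diagnosis=record.diagnosis,
    )


def score_cohort(
    records: Iterable[PatientRecord], config: InstrumentConfig | None = None
) -> pd.DataFrame:
    """Score a cohort into a tidy frame (one row per patient)."""
    config = config or default_instrument()
    rows = []
    for rec in records:
        sp = score_record(rec, config)
        row: dict[str, object] = {
            "patient_id": sp.patient_id,
            "diagnosis": sp.diagnosis.value if sp.diagnosis else None,
            "total": sp.total,
            "zone": sp.zone.value,
        }
        for sec in config.sections:
            row[f"raw_{sec.name}"] = sp.section_raw.get(sec.name, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


class InstrumentScorer(TransformerMixin, BaseEstimator):
    """Stateless transformer turning patient records into scored totals.

    Parameters
    ----------
    config : InstrumentConfig, optional
        Instrument definition; the packaged default when omitted.
    include_edss : bool, optional
        Override the config's algorithm variant without mutating it.

    Attributes
    ----------
    config_ : InstrumentConfig
        Resolved configuration after :meth:`fit`.
    section_max_ : dict
        Attainable raw maximum per section under the active variant.
    """

    def __init__(
        self,
        config: InstrumentConfig | None = None,
        include_edss: bool | None = None,
    ):
        self.config = config
        self.include_edss = include_edss

    def fit(self, X=None, y=None):
        cfg = self.config or default_instrument()
        if self.include_edss is not None:
            cfg = cfg.with_variant(self.include_edss)
        self.config_ = cfg
        self.section_max_ = cfg.section_max()
        return self

    def transform(self, X) -> pd.DataFrame:
        """Score records.

        ``X`` may be an iterable of :class:`PatientRecord` or a cohort
        DataFrame in the CSV schema (see :func:`read_cohort_csv`).
        """
        check_is_fitted(self, "config_")
        if isinstance(X, pd.DataFrame):
            X = frame_to_records(X)
        return score_cohort(X, self.config_)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_RESP_PREFIX = "resp_"


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "patient_id": r.patient_id,
            "diagnosis": r.diagnosis.value,
            "age": r.age,
            "edss": r.edss,
            "relapse_6mo": None if r.relapse_6mo is None else int(r.relapse_6mo),
            "total_score": r.total_score_override,
            "t25fw": r.t25fw,
        }
        for item_id, level in r.responses.items():
            row[_RESP_PREFIX + item_id] = level
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    resp_cols = [c for c in df.columns if c.startswith(_RESP_PREFIX)]
    records = []
    for _, row in df.iterrows():
        responses = {
            c[len(_RESP_PREFIX):]: int(row[c])
            for c in resp_cols
            if pd.notna(row[c])
        }
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                diagnosis=Diagnosis(row["diagnosis"]),
                age=None if pd.isna(row.get("age")) else float(row["age"]),
                edss=None if pd.isna(row.get("edss")) else float(row["edss"]),
                relapse_6mo=(
                    None
                    if pd.isna(row.get("relapse_6mo"))
                    else bool(int(row["relapse_6mo"]))
                ),
                responses=responses,
                total_score_override=(
                    None
                    if pd.isna(row.get("total_score"))
                    else float(row["total_score"])
                ),
                t25fw=None if pd.isna(row.get("t25fw")) else float(row["t25fw"]),
            )
        )
    return records


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    """Read a patient-record CSV (missing values as empty cells)."""
    return frame_to_records(pd.read_csv(path))


def write_cohort_csv(records: Sequence[PatientRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_scored_csv(scored: pd.DataFrame, path: str | Path) -> None:
    """Write scored output, rounding totals to 1 decimal at serialization."""
    out = scored.copy()
    out["total"] = out["total"].round(1)
    for c in out.columns:
        if c.startswith("raw_"):
            out[c] = out[c].round(1)
    out.to_csv(path, index=False)
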