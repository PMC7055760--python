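"""Declarative definition of a multi-section progression instrument.

The instrument is a physician-completed questionnaire with three sections —
disease activity, symptoms, and the impact of those symptoms on daily
living — whose raw section scores are summed and rescaled to a standardized
0–100 total.  Two cut-offs on that scale induce a traffic-light
classification: totals at or below the lower cut-off read as
relapsing-remitting MS (RRMS), totals at or above the upper cut-off as
secondary progressive MS (SPMS), and the band in between as a patient
possibly transitioning between the two courses.

Everything about the instrument — sections, items, per-level weights, the
EDSS variant, and the active cut-off pair — is data, loaded from YAML or
JSON, so alternative weightings can be evaluated without code changes.  The
default configuration shipped with the package uses ordinal none/mild/
moderate/severe levels with unit weights; the deployed instrument's exact
weights are proprietary and are not reproduced here.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterator, Literal

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "ItemDef",
    "SectionDef",
    "CutoffPair",
    "InstrumentConfig",
    "load_instrument",
    "default_instrument",
    "EDSS_ITEM_ID",
]

#: Item id whose response level is derived from the patient's EDSS score
#: (level = EDSS / 0.5) when no explicit response is recorded.
EDSS_ITEM_ID = "edss"

SectionName = Literal["disease_activity", "symptoms", "impacts"]


class ItemDef(BaseModel):
    """A single instrument item with ordinal response levels 0..L.

    ``weights[l]`` is the raw-score contribution of response level ``l``;
    level 0 always means "absent" and conventionally carries weight 0.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    weights: tuple[float, ...]
    optional: bool = False

    @field_validator("weights")
    @classmethod
    def _check_weights(cls, w: tuple[float, ...]) -> tuple[float, ...]:
        if len(w) < 2:
            raise ValueError("an item needs at least two response levels")
        if any(x < 0 for x in w):
            raise ValueError("item weights must be non-negative")
        return w

    @property
    def n_levels(self) -> int:
        """Number of response levels (levels are 0 .. n_levels - 1)."""
        return len(self.weights)

    @property
    def max_weight(self) -> float:
        return max(self.weights)

    def weight(self, level: int) -> float:
        if not 0 <= level < self.n_levels:
            raise ValueError(
                f"response {level} out of range 0..{self.n_levels - 1} "
                f"for item {self.id!r}"
            )
        return self.weights[level]


class SectionDef(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: SectionName
    items: tuple[ItemDef, ...]

    @model_validator(mode="after")
    def _check_items(self) -> "SectionDef":
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate item ids in section {self.name!r}")
        if not any(it.max_weight > 0 for it in self.items):
            raise ValueError(
                f"section {self.name!r} has no strictly positive weight; "
                "its max attainable raw score would be 0"
            )
        return self

    def max_raw(self, *, include: set[str] | None = None) -> float:
        """Max attainable raw score, optionally restricted to ``include`` ids."""
        return sum(
            it.max_weight
            for it in self.items
            if include is None or it.id in include
        )


class CutoffPair(BaseModel):
    """Lower/upper thresholds on the standardized 0–100 scale."""

    model_config = ConfigDict(frozen=True)

    lower: float
    upper: float

    @model_validator(mode="after")
    def _check_order(self) -> "CutoffPair":
        if not (0 < self.lower < self.upper < 100):
            raise ValueError(
                f"cut-offs must satisfy 0 < lower < upper < 100, "
                f"got ({self.lower}, {self.upper})"
            )
        return self


class InstrumentConfig(BaseModel):
    """Full instrument definition: sections, EDSS variant, cut-offs.

    Parameters
    ----------
    sections
        Ordered section definitions; names must be unique and item ids
        unique across the whole instrument.
    include_edss
        When True the EDSS-derived item participates in the score ("with
        EDSS" algorithm variant); when False it is dropped from both the
        numerator and the attainable maximum.
    cutoffs
        Active lower/upper cut-off pair for zone classification.
    score_max
        Standardized ceiling; fixed at 100 by convention.
    normalize_sections
        When True each section is rescaled to equal weight before pooling
        (mean of per-section fractions); default is the published pooled
        rescale of the summed raw scores.
    """

    model_config = ConfigDict(frozen=True)

    name: str = "ms-progression-instrument"
    sections: tuple[SectionDef, ...]
    include_edss: bool = True
    cutoffs: CutoffPair
    score_max: float = 100.0
    normalize_sections: bool = False

    @model_validator(mode="after")
    def _check_sections(self) -> "InstrumentConfig":
        names = [s.name for s in self.sections]
        if len(set(names)) != len(names):
            raise ValueError("section names must be unique")
        ids = [it.id for it in self.iter_items()]
        if len(set(ids)) != len(ids):
            raise ValueError("every item must belong to exactly one section")
        if self.score_max <= 0:
            raise ValueError("score_max must be positive")
        return self

    # -- convenience accessors -------------------------------------------

    def iter_items(self) -> Iterator[ItemDef]:
        for sec in self.sections:
            yield from sec.items

    def item(self, item_id: str) -> ItemDef:
        for it in self.iter_items():
            if it.id == item_id:
                return it
        raise KeyError(f"unknown item id {item_id!r}")

    def scored_item_ids(self) -> set[str]:
        """Ids of items that enter the score under the active variant."""
        ids = {it.id for it in self.iter_items()}
        if not self.include_edss:
            ids.discard(EDSS_ITEM_ID)
        return ids

    def section_max(self) -> dict[str, float]:
        include = self.scored_item_ids()
        return {s.name: s.max_raw(include=include) for s in self.sections}

    def total_max(self) -> float:
        return sum(self.section_max().values())

    def with_variant(self, include_edss: bool) -> "InstrumentConfig":
        if include_edss == self.include_edss:
            return self
        return self.model_copy(update={"include_edss": include_edss})


def load_instrument(path: str | Path) -> InstrumentConfig:
    """Load an instrument definition from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return InstrumentConfig.model_validate(data)


def default_instrument(include_edss: bool = True) -> InstrumentConfig:
    """The packaged default instrument.

    Seven symptom items and five impact items on 0–3 none/mild/moderate/
    severe levels with unit weights, a 0–3 relapse-count item, and an
    EDSS item contributing its raw 0–10 value (half-point levels).  The
    default cut-off pair (51.6, 58.9) is the with-EDSS pair derived by
    the sum-of-squares criterion in the instrument's validation study.
    """
    data = yaml.safe_load(
        resources.files("mstriage.data")
        .joinpath("default_instrument.yaml")
        .read_text()
    )
    cfg = InstrumentConfig.model_validate(data)
    return cfg.with_variant(include_edss)
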