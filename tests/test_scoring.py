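import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mstriage import (
    CutoffPair,
    Diagnosis,
    PatientRecord,
    Zone,
    classify_zone,
    score_record,
    score_sections,
    standardize_total,
)
from mstriage.scoring import (
    InstrumentScorer,
    frame_to_records,
    read_cohort_csv,
    records_to_frame,
    write_cohort_csv,
)


def _record(responses, **kw):
    kw.setdefault("patient_id", "p1")
    kw.setdefault("diagnosis", Diagnosis.RRMS)
    return PatientRecord(responses=responses, **kw)


def _full_responses(config, level_fn):
    """Responses covering every configured item at level_fn(item)."""
    return {it.id: level_fn(it) for it in config.iter_items()}


class TestScoreSections:
    def test_all_absent_scores_zero(self, default_config):
        rec = _record(_full_responses(default_config, lambda it: 0))
        assert all(v == 0 for v in score_sections(rec, default_config).values())

    def test_saturation_reaches_section_max(self, default_config):
        rec = _record(_full_responses(default_config, lambda it: it.n_levels - 1))
        raw = score_sections(rec, default_config)
        assert raw == default_config.section_max()

    def test_hand_sum_three_item_section(self, tiny_config):
        # unit weights per level: responses (1, 0, 2) -> raw 3
        rec = _record({"item0": 1, "item1": 0, "item2": 2})
        assert score_sections(rec, tiny_config) == {"symptoms": 3}

    def test_unknown_item_named_in_error(self, tiny_config):
        rec = _record({"item0": 1, "item1": 0, "item2": 0, "ghost": 1})
        with pytest.raises(ValueError, match="ghost"):
            score_sections(rec, tiny_config)

    def test_response_out_of_range_rejected(self, tiny_config):
        rec = _record({"item0": 5, "item1": 0, "item2": 0})
        with pytest.raises(ValueError, match="item0"):
            score_sections(rec, tiny_config)

    def test_missing_required_response_rejected(self, tiny_config):
        rec = _record({"item0": 1})
        with pytest.raises(ValueError, match="missing response"):
            score_sections(rec, tiny_config)

    def test_edss_response_derived_from_edss_field(self, default_config):
        responses = _full_responses(default_config, lambda it: 0)
        del responses["edss"]
        rec = _record(responses, edss=6.5)
        raw = score_sections(rec, default_config)
        assert raw["disease_activity"] == pytest.approx(6.5)


class TestStandardizeTotal:
    def test_extremes(self, default_config):
        assert standardize_total(default_config.section_max(), default_config) == 100
        zeros = {s.name: 0.0 for s in default_config.sections}
        assert standardize_total(zeros, default_config) == 0

    def test_pooled_rescale(self, tiny_config):
        # raw sum 27 of max 60 -> 45.0 (two extra sections to reach max 60)
        from mstriage import InstrumentConfig, ItemDef, SectionDef

        cfg = InstrumentConfig(
            sections=(
                SectionDef(name="disease_activity",
                           items=(ItemDef(id="a", weights=tuple(range(21))),)),
                SectionDef(name="symptoms",
                           items=(ItemDef(id="b", weights=tuple(range(21))),)),
                SectionDef(name="impacts",
                           items=(ItemDef(id="c", weights=tuple(range(21))),)),
            ),
            include_edss=False,
            cutoffs=CutoffPair(lower=40, upper=60),
        )
        total = standardize_total(
            {"disease_activity": 10, "symptoms": 10, "impacts": 7}, cfg
        )
        assert total == pytest.approx(45.0)

    def test_mismatched_sections_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="sections"):
            standardize_total({"impacts": 1.0}, tiny_config)


class TestClassifyZone:
    CUTS = CutoffPair(lower=46.3, upper=57.8)

    @pytest.mark.parametrize(
        "total,expected",
        [
            (38.1, Zone.GREEN_RRMS),        # mean RRMS score below lower cut-off
            (46.3, Zone.GREEN_RRMS),        # lower boundary inclusive
            (57.8, Zone.RED_SPMS),          # "equal or above the upper cut-off"
            (50.0, Zone.YELLOW_TRANSITIONING),
            (0.0, Zone.GREEN_RRMS),
            (100.0, Zone.RED_SPMS),
        ],
    )
    def test_boundaries(self, total, expected):
        assert classify_zone(total, self.CUTS) == expected

    @given(
        total=st.floats(0, 100),
        lower=st.floats(1, 98),
        width=st.floats(0.5, 50),
    )
    def test_zones_partition_the_scale(self, total, lower, width):
        upper = min(lower + width, 99.5)
        if upper <= lower:
            return
        cuts = CutoffPair(lower=lower, upper=upper)
        zone = classify_zone(total, cuts)
        expected = (
            Zone.GREEN_RRMS
            if total <= lower
            else Zone.RED_SPMS
            if total >= upper
            else Zone.YELLOW_TRANSITIONING
        )
        assert zone == expected


@st.composite
def _response_sets(draw):
    from mstriage import default_instrument

    cfg = default_instrument()
    responses = {
        it.id: draw(st.integers(0, it.n_levels - 1)) for it in cfg.iter_items()
    }
    return cfg, responses


class TestScoreProperties:
    @given(_response_sets())
    def test_monotone_in_every_response(self, cfg_responses):
        cfg, responses = cfg_responses
        base = score_record(_record(responses), cfg).total
        for it in cfg.iter_items():
            if responses[it.id] + 1 >= it.n_levels:
                continue
            bumped = dict(responses, **{it.id: responses[it.id] + 1})
            assert score_record(_record(bumped), cfg).total >= base

    @given(_response_sets(), st.floats(0.1, 10))
    def test_weight_scale_invariance(self, cfg_responses, c):
        cfg, responses = cfg_responses
        scaled = cfg.model_copy(
            update={
                "sections": tuple(
                    s.model_copy(
                        update={
                            "items": tuple(
                                it.model_copy(
                                    update={"weights": tuple(c * w for w in it.weights)}
                                )
                                for it in s.items
                            )
                        }
                    )
                    for s in cfg.sections
                )
            }
        )
        t0 = score_record(_record(responses), cfg).total
        t1 = score_record(_record(responses), scaled).total
        assert t1 == pytest.approx(t0, abs=1e-9)

    @given(_response_sets())
    def test_total_bounded(self, cfg_responses):
        cfg, responses = cfg_responses
        assert 0 <= score_record(_record(responses), cfg).total <= 100


class TestScorerAndIO:
    def test_override_bypasses_items(self, default_config):
        rec = _record({}, total_score_override=55.2)
        scored = score_record(rec, default_config)
        assert scored.total == 55.2
        assert scored.zone == Zone.YELLOW_TRANSITIONING

    def test_transformer_roundtrip(self, default_config):
        recs = [
            _record(_full_responses(default_config, lambda it: 1),
                    patient_id=f"p{i}")
            for i in range(3)
        ]
        scorer = InstrumentScorer(default_config).fit()
        out = scorer.transform(recs)
        assert list(out["patient_id"]) == ["p0", "p1", "p2"]
        assert out["total"].nunique() == 1

    def test_sklearn_params_contract(self):
        scorer = InstrumentScorer()
        params = scorer.get_params()
        assert set(params) == {"config", "include_edss"}
        scorer.set_params(include_edss=False).fit()
        assert scorer.config_.include_edss is False

    def test_csv_roundtrip(self, tmp_path, default_config):
        recs = [
            _record(_full_responses(default_config, lambda it: 2),
                    patient_id="a", edss=4.5, relapse_6mo=True, age=44.0),
            _record({}, patient_id="b", total_score_override=69.6,
                    diagnosis=Diagnosis.SPMS),
        ]
        path = tmp_path / "cohort.csv"
        write_cohort_csv(recs, path)
        loaded = read_cohort_csv(path)
        assert loaded == recs
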