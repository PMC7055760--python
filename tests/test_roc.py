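import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import roc_auc_score

from mstriage import (
    DualCutoffClassifier,
    LabelledScores,
    ROCCurve,
    auc,
    dual_cutoffs,
    empirical_roc,
    sample_size_auc,
    sens_spec_at,
    sum_squares_cutoff,
    youden_cutoff,
)


def pair_count_auc(pos, neg):
    """Independent oracle: exhaustive concordant-pair counting, ties 1/2."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def trapezoid_auc(curve):
    fpr = 1 - curve.spec
    order = np.lexsort((curve.sens, fpr))  # ascending fpr, then tpr
    return float(np.trapezoid(curve.sens[order], fpr[order]))


def _data(pos, neg, orientation="higher_is_positive"):
    scores = np.concatenate([pos, neg]).astype(float)
    labels = np.r_[np.ones(len(pos), bool), np.zeros(len(neg), bool)]
    return LabelledScores(scores, labels, orientation)


class TestAUC:
    def test_hand_example_five_sixths(self):
        data = _data([3, 5], [1, 2, 4])
        assert auc(data).auc == pytest.approx(5 / 6)
        assert trapezoid_auc(empirical_roc(data)) == pytest.approx(5 / 6)

    def test_single_tied_pair_is_half(self):
        assert auc(_data([2], [2])).auc == 0.5

    def test_null_case_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        assert auc(LabelledScores(scores, labels)).auc == pytest.approx(0.5, abs=0.05)

    def test_matches_sklearn_with_ties(self, rng):
        scores = rng.integers(0, 6, 300).astype(float)
        labels = rng.random(300) < 0.4
        ours = auc(LabelledScores(scores, labels)).auc
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_ci_brackets_point_estimate(self, rng):
        data = _data(rng.normal(1, 1, 50), rng.normal(0, 1, 80))
        for method in ("hanley-mcneil", "delong"):
            res = auc(data, ci_method=method)
            assert res.ci_low <= res.auc <= res.ci_high
            assert 0 <= res.ci_low and res.ci_high <= 1

    def test_single_class_error_names_missing_class(self):
        with pytest.raises(ValueError, match="negative class"):
            LabelledScores(np.array([1.0, 2.0]), np.array([True, True]))
        with pytest.raises(ValueError, match="positive class"):
            LabelledScores(np.array([1.0, 2.0]), np.array([False, False]))

    def test_closed_form_mixture_agreement(self, rng):
        # normal model: AUC = weighted Phi of standardized mean differences
        m_pos, s_pos = 69.6, 12.0
        parts = [(89, 38.1, 12.5), (47, 55.2, 11.1)]
        w = np.array([n for n, *_ in parts], float)
        closed = sum(
            wi * stats.norm.cdf((m_pos - m) / np.hypot(s_pos, s))
            for wi, (_, m, s) in zip(w / w.sum(), parts)
        )
        sims = []
        for seed in range(200):
            r = np.random.default_rng(seed)
            neg = np.concatenate(
                [r.normal(m, s, n) for n, m, s in parts]
            )
            pos = r.normal(m_pos, s_pos, 62)
            sims.append(auc(_data(pos, neg)).auc)
        assert np.mean(sims) == pytest.approx(closed, abs=0.005)


class TestCurveAndCutoffs:
    def test_curve_monotone_with_endpoints(self, rng):
        data = _data(rng.normal(1, 1, 40), rng.normal(0, 1, 60))
        curve = empirical_roc(data)
        assert np.all(np.diff(curve.sens) <= 0)
        assert np.all(np.diff(curve.spec) >= 0)
        assert curve.sens[0] == 1 and curve.spec[0] == 0
        assert curve.sens[-1] == 0 and curve.spec[-1] == 1

    def test_perfect_separation_has_perfect_threshold(self):
        curve = empirical_roc(_data([10, 11], [1, 2, 3]))
        j = youden_cutoff(curve)
        assert (j.sensitivity, j.specificity) == (1.0, 1.0)
        assert j.criterion_value == 1.0
        assert sum_squares_cutoff(curve).criterion_value == 0.0

    def test_uninformative_scores_tie_break_smallest(self):
        curve = empirical_roc(_data([5, 5], [5, 5, 5]))
        est = youden_cutoff(curve)
        assert est.criterion_value == pytest.approx(0.0)
        assert est.threshold == curve.thresholds.min()

    def test_criterion_arithmetic_from_reported_operating_points(self):
        # J at (sens .90, spec .63) = .53; SS at (sens .79, spec .74) = .1117
        curve = ROCCurve(
            thresholds=np.array([1.0, 2.0, 3.0]),
            sens=np.array([1.0, 0.90, 0.0]),
            spec=np.array([0.0, 0.63, 1.0]),
        )
        assert youden_cutoff(curve).criterion_value == pytest.approx(0.53)
        curve2 = ROCCurve(
            thresholds=np.array([1.0, 2.0, 3.0]),
            sens=np.array([1.0, 0.79, 0.0]),
            spec=np.array([0.0, 0.74, 1.0]),
        )
        est = sum_squares_cutoff(curve2)
        assert est.threshold == 2.0
        assert est.criterion_value == pytest.approx(0.1117)

    def test_sum_squares_on_concave_toy_curve(self):
        curve = ROCCurve(
            thresholds=np.array([1.0, 2.0, 3.0]),
            sens=np.array([1.0, 0.8, 0.5]),
            spec=np.array([0.5, 0.9, 1.0]),
        )
        assert sum_squares_cutoff(curve).threshold == 2.0

    @given(st.integers(0, 1000))
    def test_orientation_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 10, 30).astype(float)
        labels = rng.random(30) < 0.5
        if labels.all() or not labels.any():
            return
        hi = LabelledScores(scores, labels, "higher_is_positive")
        lo = LabelledScores(-scores, labels, "lower_is_positive")
        assert auc(hi).auc == pytest.approx(auc(lo).auc, abs=1e-12)
        j_hi, j_lo = youden_cutoff(empirical_roc(hi)), youden_cutoff(empirical_roc(lo))
        assert j_hi.criterion_value == pytest.approx(j_lo.criterion_value, abs=1e-12)
        assert j_hi.sensitivity == pytest.approx(j_lo.sensitivity, abs=1e-12)
        t = float(rng.uniform(-1, 10))
        assert sens_spec_at(hi, t) == pytest.approx(sens_spec_at(lo, -t), abs=1e-12)


class TestSensSpecAt:
    def test_threshold_below_all_scores(self):
        data = _data([3, 5], [1, 2])
        assert sens_spec_at(data, 0.5) == (1.0, 0.0)

    def test_direct_count(self):
        data = _data([60, 70], [40, 50])
        assert sens_spec_at(data, 55) == (1.0, 1.0)

    def test_boundary_inclusive(self):
        data = _data([58.9], [58.9])
        sens, spec = sens_spec_at(data, 58.9)
        assert sens == 1.0 and spec == 0.0


class TestDualCutoffs:
    @staticmethod
    def _scored(rng, shift=0.0):
        rows = []
        for diag, mean, sd, n in (
            ("RRMS", 38.1, 12.5, 89),
            ("TRANSITIONING", 55.2, 11.1, 47),
            ("SPMS", 69.6, 12.0, 62),
        ):
            for t in rng.normal(mean + shift, sd, n):
                rows.append({"diagnosis": diag, "total": np.clip(t, 0, 100)})
        return pd.DataFrame(rows)

    def test_perfectly_ordered_groups_bracket_transitioning(self):
        scored = pd.DataFrame(
            {
                "diagnosis": ["RRMS"] * 3 + ["TRANSITIONING"] * 3 + ["SPMS"] * 3,
                "total": [10, 20, 30, 45, 50, 55, 70, 80, 90],
            }
        )
        res = dual_cutoffs(scored)
        pair = res.cutoff_pair("sum_squares")
        assert 30 < pair.lower < 45
        assert 55 < pair.upper < 70

    def test_missing_group_error_names_it(self):
        scored = pd.DataFrame(
            {"diagnosis": ["RRMS", "SPMS"], "total": [30.0, 80.0]}
        )
        with pytest.raises(ValueError, match="TRANSITIONING"):
            dual_cutoffs(scored)

    def test_lower_positive_flip_keeps_thresholds(self, rng):
        scored = self._scored(rng)
        default = dual_cutoffs(scored, lower_positive="non_rrms")
        flipped = dual_cutoffs(scored, lower_positive="rrms")
        for m in ("youden", "sum_squares"):
            assert default.lower[m].threshold == pytest.approx(
                flipped.lower[m].threshold
            )
            # sens/spec roles swap when the positive class flips
            assert default.lower[m].sensitivity == pytest.approx(
                flipped.lower[m].specificity, abs=1e-12
            )

    def test_classifier_fit_predict(self, rng):
        scored = self._scored(rng)
        clf = DualCutoffClassifier(method="sum_squares").fit(
            scored["total"], scored["diagnosis"]
        )
        assert clf.lower_ < clf.upper_
        zones = clf.predict([10.0, (clf.lower_ + clf.upper_) / 2, 95.0])
        assert list(zones) == [
            "GREEN_RRMS", "YELLOW_TRANSITIONING", "RED_SPMS",
        ]
        assert set(clf.get_params()) == {
            "method", "variant", "lower_positive", "threshold_grid",
        }


class TestSampleSize:
    def test_decreasing_in_effect_size(self):
        ns = [sample_size_auc(a) for a in (0.60, 0.68, 0.80, 0.95)]
        assert ns == sorted(ns, reverse=True)

    def test_increasing_in_power(self):
        assert sample_size_auc(0.68, power=0.90) > sample_size_auc(0.68, power=0.50)

    def test_design_value_plausible(self):
        # the planned design detected AUC >= 0.68 at alpha .025, power .90;
        # the prespecified target of >150 patients exceeds this minimum
        n = sample_size_auc(0.68, alpha=0.025, power=0.90)
        assert 80 <= n <= 155

    def test_invalid_parameters_rejected(self):
        for kwargs in (
            {"auc_alt": 0.4}, {"auc_alt": 1.0},
            {"auc_alt": 0.7, "alpha": 0}, {"auc_alt": 0.7, "power": 1.0},
        ):
            with pytest.raises(ValueError):
                sample_size_auc(**kwargs)
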