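"""Empirical ROC curves, AUC, optimal cut-offs, and the dual-cut-off rule.

The instrument's validation runs two ROC analyses on the standardized
total: SPMS versus the pooled RRMS + transitioning group gives the *upper*
cut-off, and RRMS versus the pooled transitioning + SPMS group gives the
*lower* cut-off.  For each comparison the optimal threshold is estimated by
two criteria that weight sensitivity and specificity equally:

* Youden's J = sens + spec - 1, maximized;
* the sum-of-squares distance SS = (1 - sens)^2 + (1 - spec)^2 to the
  perfect-classifier corner, minimized.

AUC is the normalized Mann-Whitney U statistic (ties counted 1/2), which
equals the trapezoidal area under the empirical curve; its confidence
interval uses the Hanley-McNeil standard error by default, with DeLong
available behind a flag.  Candidate thresholds are midpoints between
consecutive distinct observed scores plus sentinels beyond the extremes
(observed values available via ``threshold_grid="observed"``), and the
positivity rule is boundary inclusive: score >= threshold reads positive
under ``higher_is_positive``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .instrument import CutoffPair
from .scoring import Diagnosis, Zone, classify_zone

__all__ = [
    "LabelledScores",
    "ROCCurve",
    "CutoffEstimate",
    "AUCResult",
    "DualCutoffResult",
    "empirical_roc",
    "auc",
    "youden_cutoff",
    "sum_squares_cutoff",
    "sens_spec_at",
    "dual_cutoffs",
    "sample_size_auc",
    "DualCutoffClassifier",
]

Orientation = Literal["higher_is_positive", "lower_is_positive"]


@dataclass(frozen=True)
class LabelledScores:
    """Parallel score/label arrays for a two-class comparison."""

    scores: np.ndarray
    labels: np.ndarray  # boolean, True = positive class
    orientation: Orientation = "higher_is_positive"

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels, dtype=bool)
        if scores.ndim != 1 or labels.ndim != 1 or len(scores) != len(labels):
            raise ValueError("scores and labels must be parallel 1-d arrays")
        if not labels.any():
            raise ValueError("positive class is empty")
        if labels.all():
            raise ValueError("negative class is empty")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.labels).sum())

    def oriented(self) -> "LabelledScores":
        """Equivalent problem with higher_is_positive orientation."""
        if self.orientation == "higher_is_positive":
            return self
        return LabelledScores(-self.scores, self.labels, "higher_is_positive")


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC evaluated on a threshold grid (ascending thresholds).

    ``sens[i]``/``spec[i]`` are the sensitivity and specificity of the rule
    "positive iff score >= thresholds[i]" (or <= for lower_is_positive, in
    which case thresholds descend in the original score units but the
    stored grid ascends in oriented units and is reported back-transformed).
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    orientation: Orientation = "higher_is_positive"


@dataclass(frozen=True)
class CutoffEstimate:
    method: str
    threshold: float
    sensitivity: float
    specificity: float
    criterion_value: float


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    se: float
    ci_method: str = "hanley-mcneil"


@dataclass(frozen=True)
class DualCutoffResult:
    """Upper (SPMS vs rest) and lower (RRMS vs rest) cut-off estimates.

    ``upper`` and ``lower`` map estimation method -> CutoffEstimate; lower
    thresholds are expressed in original score units regardless of which
    class was treated as positive.  ``consistent[method]`` is False when
    the selected pair violates lower < upper (flagged, never swapped).
    """

    upper: dict[str, CutoffEstimate]
    lower: dict[str, CutoffEstimate]
    auc_upper: AUCResult
    auc_lower: AUCResult
    variant: str
    lower_positive: str

    @property
    def consistent(self) -> dict[str, bool]:
        return {
            m: self.lower[m].threshold < self.upper[m].threshold
            for m in self.upper
            if m in self.lower
        }

    def cutoff_pair(self, method: str = "sum_squares") -> CutoffPair:
        lo, hi = self.lower[method].threshold, self.upper[method].threshold
        if not lo < hi:
            raise ValueError(
                f"derived cut-offs inconsistent for {method!r}: "
                f"lower {lo} >= upper {hi}"
            )
        return CutoffPair(lower=lo, upper=hi)


# ---------------------------------------------------------------------------
# curve construction and summary statistics
# ---------------------------------------------------------------------------


def _threshold_grid(scores: np.ndarray, kind: str) -> np.ndarray:
    distinct = np.unique(scores)
    if kind == "observed":
        inner = distinct
    elif kind == "midpoint":
        inner = (distinct[:-1] + distinct[1:]) / 2 if len(distinct) > 1 else np.array([])
    else:
        raise ValueError(f"unknown threshold grid {kind!r}")
    lo = distinct[0] - 1.0  # sentinel below min: everything positive
    hi = distinct[-1] + 1.0  # sentinel above max: nothing positive
    return np.concatenate([[lo], inner, [hi]])


def empirical_roc(
    data: LabelledScores, threshold_grid: str = "midpoint"
) -> ROCCurve:
    """Empirical ROC over midpoint thresholds plus sentinels.

    Sensitivity is P(score >= t | positive) and specificity
    P(score < t | negative) in oriented units; a ``lower_is_positive``
    input mirrors by negation and reports thresholds back in original
    units (rule: positive iff score <= threshold).
    """
    orient = data.oriented()
    thr = _threshold_grid(orient.scores, threshold_grid)
    pos = orient.scores[orient.labels]
    neg = orient.scores[~orient.labels]
    sens = (pos[None, :] >= thr[:, None]).mean(axis=1)
    spec = (neg[None, :] < thr[:, None]).mean(axis=1)
    if data.orientation == "lower_is_positive":
        thr = -thr
    return ROCCurve(thr, sens, spec, data.orientation)


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    n_pos, n_neg = len(pos), len(neg)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _hanley_mcneil_se(a: float, n_pos: int, n_neg: int) -> float:
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (
        a * (1 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def _delong_se(pos: np.ndarray, neg: np.ndarray, a: float) -> float:
    # structural components: V10 for positives, V01 for negatives
    v10 = np.array([
        ((p > neg).mean() + 0.5 * (p == neg).mean()) for p in pos
    ])
    v01 = np.array([
        ((pos > n).mean() + 0.5 * (pos == n).mean()) for n in neg
    ])
    var = np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg)
    return math.sqrt(max(var, 0.0))


def auc(
    data: LabelledScores,
    alpha: float = 0.05,
    ci_method: Literal["hanley-mcneil", "delong"] = "hanley-mcneil",
) -> AUCResult:
    """AUC as the normalized Mann-Whitney U statistic with ties at 1/2.

    Equals the trapezoidal area under :func:`empirical_roc`; the normal
    confidence interval is clamped to [0, 1].
    """
    orient = data.oriented()
    pos = orient.scores[orient.labels]
    neg = orient.scores[~orient.labels]
    a = _mann_whitney_auc(pos, neg)
    if ci_method == "hanley-mcneil":
        se = _hanley_mcneil_se(a, len(pos), len(neg))
    elif ci_method == "delong":
        se = _delong_se(pos, neg, a)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    z = stats.norm.ppf(1 - alpha / 2)
    return AUCResult(
        auc=a,
        ci_low=max(0.0, a - z * se),
        ci_high=min(1.0, a + z * se),
        n_pos=len(pos),
        n_neg=len(neg),
        se=se,
        ci_method=ci_method,
    )


def _select(curve: ROCCurve, criterion: np.ndarray, best: str, method: str) -> CutoffEstimate:
    # deterministic tie-break: smallest threshold among criterion ties,
    # taken on the oriented scale so the choice is orientation-invariant
    mask = criterion == (criterion.max() if best == "max" else criterion.min())
    idx = np.flatnonzero(mask)
    key = (
        curve.thresholds
        if curve.orientation == "higher_is_positive"
        else -curve.thresholds
    )
    i = idx[np.argmin(key[idx])]
    return CutoffEstimate(
        method=method,
        threshold=float(curve.thresholds[i]),
        sensitivity=float(curve.sens[i]),
        specificity=float(curve.spec[i]),
        criterion_value=float(criterion[i]),
    )


def youden_cutoff(curve: ROCCurve) -> CutoffEstimate:
    """Threshold maximizing Youden's J = sens + spec - 1."""
    j = curve.sens + curve.spec - 1
    return _select(curve, j, "max", "youden")


def sum_squares_cutoff(curve: ROCCurve) -> CutoffEstimate:
    """Threshold minimizing (1 - sens)^2 + (1 - spec)^2."""
    ss = (1 - curve.sens) ** 2 + (1 - curve.spec) ** 2
    return _select(curve, ss, "min", "sum_squares")


def sens_spec_at(data: LabelledScores, threshold: float) -> tuple[float, float]:
    """Sensitivity/specificity of the boundary-inclusive rule at a threshold.

    Under ``higher_is_positive``: positive iff score >= threshold; mirrored
    for ``lower_is_positive`` (positive iff score <= threshold).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pos = data.scores[data.labels]
    neg = data.scores[~data.labels]
    if data.orientation == "higher_is_positive":
        return float((pos >= threshold).mean()), float((neg < threshold).mean())
    return float((pos <= threshold).mean()), float((neg > threshold).mean())


# ---------------------------------------------------------------------------
# dual-cut-off derivation
# ---------------------------------------------------------------------------

_METHODS = {"youden": youden_cutoff, "sum_squares": sum_squares_cutoff}


def _labelled(
    totals: np.ndarray, diagnosis: np.ndarray, positive: set[str], orientation: Orientation
) -> LabelledScores:
    labels = np.isin(diagnosis, list(positive))
    return LabelledScores(totals, labels, orientation)


def dual_cutoffs(
    scored: pd.DataFrame,
    variant: str = "with_edss",
    lower_positive: Literal["non_rrms", "rrms"] = "non_rrms",
    threshold_grid: str = "midpoint",
    ci_method: str = "hanley-mcneil",
) -> DualCutoffResult:
    """Derive the upper and lower cut-offs from a scored cohort.

    Upper: SPMS (positive) versus pooled RRMS + transitioning, higher
    scores positive.  Lower: RRMS versus pooled transitioning + SPMS; by
    default the pooled non-RRMS group is the positive class under
    ``higher_is_positive`` (``lower_positive="rrms"`` flips to RRMS as
    the positive class with lower scores positive — same thresholds,
    sens/spec roles exchanged).

    ``scored`` needs columns ``total`` and ``diagnosis``.  Both estimation
    methods are computed for each cut-off; an inconsistent pair
    (lower >= upper) is flagged via ``DualCutoffResult.consistent``, never
    silently reordered.
    """
    diag = scored["diagnosis"].astype(str).to_numpy()
    totals = scored["total"].to_numpy(dtype=float)
    for g in (Diagnosis.RRMS, Diagnosis.TRANSITIONING, Diagnosis.SPMS):
        if not (diag == g.value).any():
            raise ValueError(f"diagnosis group {g.value} is missing or empty")

    upper_data = _labelled(totals, diag, {"SPMS"}, "higher_is_positive")
    if lower_positive == "non_rrms":
        lower_data = _labelled(
            totals, diag, {"TRANSITIONING", "SPMS"}, "higher_is_positive"
        )
    elif lower_positive == "rrms":
        lower_data = _labelled(totals, diag, {"RRMS"}, "lower_is_positive")
    else:
        raise ValueError(f"unknown lower_positive {lower_positive!r}")

    upper_curve = empirical_roc(upper_data, threshold_grid)
    lower_curve = empirical_roc(lower_data, threshold_grid)
    upper = {m: fn(upper_curve) for m, fn in _METHODS.items()}
    lower = {m: fn(lower_curve) for m, fn in _METHODS.items()}
    result = DualCutoffResult(
        upper=upper,
        lower=lower,
        auc_upper=auc(upper_data, ci_method=ci_method),
        auc_lower=auc(lower_data, ci_method=ci_method),
        variant=variant,
        lower_positive=lower_positive,
    )
    for m, ok in result.consistent.items():
        if not ok:
            warnings.warn(
                f"{variant}/{m}: derived lower cut-off "
                f"{result.lower[m].threshold:.1f} is not below the upper "
                f"cut-off {result.upper[m].threshold:.1f}",
                stacklevel=2,
            )
    return result


# ---------------------------------------------------------------------------
# sample size for an AUC test against 0.5
# ---------------------------------------------------------------------------


def sample_size_auc(
    auc_alt: float,
    alpha: float = 0.025,
    power: float = 0.90,
    allocation_ratio: float = 1.0,
) -> int:
    """Smallest total n detecting ``auc_alt`` against H0: AUC = 0.5.

    One-sided normal test at level ``alpha`` with the Hanley-McNeil
    variance under both hypotheses; ``allocation_ratio`` is
    n_negative / n_positive.  The default alpha of .025 reflects a
    Bonferroni split of .05 over two planned ROC comparisons.
    """
    if not 0.5 < auc_alt < 1:
        raise ValueError("auc_alt must lie in (0.5, 1)")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must lie in (0, 1)")
    if allocation_ratio <= 0:
        raise ValueError("allocation_ratio must be positive")
    z_a = stats.norm.ppf(1 - alpha)
    z_b = stats.norm.ppf(power)
    for total in range(4, 100_000):
        n_pos = max(2, round(total / (1 + allocation_ratio)))
        n_neg = total - n_pos
        if n_neg < 2:
            continue
        se0 = _hanley_mcneil_se(0.5, n_pos, n_neg)
        se1 = _hanley_mcneil_se(auc_alt, n_pos, n_neg)
        if z_a * se0 + z_b * se1 <= auc_alt - 0.5:
            return total
    raise RuntimeError("sample size search did not converge")


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------


class DualCutoffClassifier(ClassifierMixin, BaseEstimator):
    """Fit the dual cut-offs on labelled totals; predict traffic-light zones.

    ``fit(X, y)`` takes standardized totals (1-d or a single-column 2-d
    array) and physician diagnosis labels, runs the two ROC comparisons and
    stores the selected cut-off pair; ``predict(X)`` applies the inclusive
    three-zone rule.

    Parameters
    ----------
    method : {"sum_squares", "youden"}
        Criterion used to select the reported pair.
    variant : str
        Label recorded in the result (e.g. "with_edss").
    lower_positive : {"non_rrms", "rrms"}
        Positive-class convention for the lower comparison.

    Attributes
    ----------
    result_ : DualCutoffResult
    lower_, upper_ : float
        Selected thresholds.
    cutoffs_ : CutoffPair
    """

    def __init__(
        self,
        method: str = "sum_squares",
        variant: str = "with_edss",
        lower_positive: str = "non_rrms",
        threshold_grid: str = "midpoint",
    ):
        self.method = method
        self.variant = variant
        self.lower_positive = lower_positive
        self.threshold_grid = threshold_grid

    @staticmethod
    def _totals(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValueError("X must be 1-d totals or a single-column array")
        return x

    def fit(self, X, y):
        totals = self._totals(X)
        diag = np.asarray([Diagnosis(v).value for v in np.asarray(y)])
        scored = pd.DataFrame({"total": totals, "diagnosis": diag})
        self.result_ = dual_cutoffs(
            scored,
            variant=self.variant,
            lower_positive=self.lower_positive,
            threshold_grid=self.threshold_grid,
        )
        self.cutoffs_ = self.result_.cutoff_pair(self.method)
        self.lower_ = self.cutoffs_.lower
        self.upper_ = self.cutoffs_.upper
        self.classes_ = np.array([z.value for z in Zone])
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "cutoffs_")
        totals = self._totals(X)
        return np.array(
            [classify_zone(t, self.cutoffs_).value for t in totals]
        )
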