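"""Reliability and construct-validity statistics, implemented from formulas.

* Interrater reliability: ICC(2,1) — two-way random effects, absolute
  agreement, single measure — from the ANOVA mean-squares decomposition,
  with the exact F-based confidence interval and the conventional
  interpretation bands (>= 0.75 excellent, 0.40–0.75 fair to good,
  < 0.40 poor).
* Known-groups validity: two-sample t tests (Welch by default, Student's
  pooled behind a flag) with Cohen's d on the pooled SD, for diagnosis
  groups and for EDSS disability bands.
* Item validity: Spearman rank correlations between item responses and the
  ordinal physician diagnosis (RRMS = 0 < transitioning = 1 < SPMS = 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import DIAGNOSIS_ORDER, Diagnosis

__all__ = [
    "ICCResult",
    "KnownGroupsResult",
    "icc_2_1",
    "icc_band",
    "known_groups",
    "welch_from_summary",
    "edss_band",
    "item_diagnosis_correlation",
    "read_rater_matrix",
]


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    band: str
    n_subjects: int
    n_raters: int
    ms_subjects: float
    ms_raters: float
    ms_error: float


@dataclass(frozen=True)
class KnownGroupsResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: float
    p: float
    cohens_d: float


def icc_band(icc: float) -> str:
    if icc >= 0.75:
        return "excellent"
    if icc >= 0.40:
        return "fair to good"
    return "poor"


def _as_grid(matrix) -> np.ndarray:
    values = (
        matrix.to_numpy(dtype=float)
        if isinstance(matrix, pd.DataFrame)
        else np.asarray(matrix, dtype=float)
    )
    if values.ndim != 2:
        raise ValueError("rater matrix must be 2-d (subjects x raters)")
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if np.isnan(values).any():
        raise ValueError("rater matrix has missing cells; no imputation is done")
    return values


def icc_2_1(matrix, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) with its exact F-based confidence interval.

    Mean squares come from the two-way crossed layout (subjects x raters,
    one observation per cell)::

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

    where MS_R, MS_C, MS_E are the subject, rater and residual mean
    squares, n subjects, k raters.  The interval follows the standard
    two-way random-effects absolute-agreement construction with a
    Satterthwaite-approximated denominator df.
    """
    values = _as_grid(matrix)
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_r = k * ((row_means - grand) ** 2).sum()
    ss_c = n * ((col_means - grand) ** 2).sum()
    ss_t = ((values - grand) ** 2).sum()
    ss_e = ss_t - ss_r - ss_c
    msr = ss_r / (n - 1)
    msc = ss_c / (k - 1)
    mse = ss_e / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if ss_r == 0 or denom <= 0:
        warnings.warn("zero between-subject variance; ICC reported as 0")
        icc = 0.0
    else:
        icc = (msr - mse) / denom

    ci_low, ci_high = _icc2_ci(icc, msr, msc, mse, n, k, alpha)
    return ICCResult(
        icc=float(icc),
        ci_low=ci_low,
        ci_high=ci_high,
        band=icc_band(icc),
        n_subjects=n,
        n_raters=k,
        ms_subjects=float(msr),
        ms_raters=float(msc),
        ms_error=float(mse),
    )


def _icc2_ci(
    icc: float, msr: float, msc: float, mse: float, n: int, k: int, alpha: float
) -> tuple[float, float]:
    if mse <= 0:
        # noiseless grid: the F-based interval degenerates to a point
        point = float(np.clip(icc, -1.0, 1.0))
        return point, point
    fj = msc / mse
    a = n * (1 + (k - 1) * icc) - k * icc
    vn = (k - 1) * (n - 1) * (k * icc * fj + a) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + a**2
    v = vn / vd if vd > 0 else 1.0
    f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
    num_l = n * (msr - f_low * mse)
    den_l = f_low * (k * msc + (k * n - k - n) * mse) + n * msr
    num_u = n * (f_up * msr - mse)
    den_u = k * msc + (k * n - k - n) * mse + n * f_up * msr
    lo = num_l / den_l if den_l != 0 else -1.0
    hi = num_u / den_u if den_u != 0 else 1.0
    return float(np.clip(lo, -1.0, 1.0)), float(np.clip(hi, -1.0, 1.0))


# ---------------------------------------------------------------------------
# known-groups validity
# ---------------------------------------------------------------------------


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    return float((a.mean() - b.mean()) / sp) if sp > 0 else 0.0


def _compare(
    label_a: str, a: np.ndarray, label_b: str, b: np.ndarray, equal_var: bool
) -> KnownGroupsResult:
    for label, x in ((label_a, a), (label_b, b)):
        if len(x) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = len(a) + len(b) - 2
    else:
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        df = (va + vb) ** 2 / (
            va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
        )
    return KnownGroupsResult(
        group_a=label_a,
        group_b=label_b,
        n_a=len(a),
        n_b=len(b),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        t=float(t),
        df=float(df),
        p=float(p),
        cohens_d=_cohens_d(a, b),
    )


def known_groups(
    groups: Mapping[str, Sequence[float]], equal_var: bool = False
) -> list[KnownGroupsResult]:
    """All pairwise two-sample t tests with Cohen's d (Welch by default).

    ``groups`` maps a group label (diagnosis or EDSS band) to its total
    scores; pairs follow the mapping's order.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    return [
        _compare(la, arrays[la], lb, arrays[lb], equal_var)
        for la, lb in combinations(arrays, 2)
    ]


def welch_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
) -> tuple[float, float, float, float]:
    """Welch t, df, two-sided p and pooled-SD Cohen's d from summary stats."""
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2 * stats.t.sf(abs(t), df)
    sp = np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2))
    d = (mean_a - mean_b) / sp
    return float(t), float(df), float(p), float(d)


def edss_band(edss: float | None) -> str | None:
    """Disability band used for known-groups contrasts.

    ``low`` covers EDSS in [1, 4.5], ``high`` EDSS in (4.5, 9.5); scores
    outside both bands (EDSS < 1 or >= 9.5, or missing) fall in neither.
    """
    if edss is None or np.isnan(edss):
        return None
    if 1.0 <= edss <= 4.5:
        return "low"
    if 4.5 < edss < 9.5:
        return "high"
    return None


# ---------------------------------------------------------------------------
# item–diagnosis correlations
# ---------------------------------------------------------------------------


def item_diagnosis_correlation(
    responses: pd.DataFrame, diagnoses: Sequence[Diagnosis | str]
) -> pd.DataFrame:
    """Spearman correlation of each item with the ordinal diagnosis.

    Average-rank tie handling (scipy's convention).  A constant item has an
    undefined correlation and is reported as NaN with band ``undefined``
    rather than coerced to 0.  Returns a frame with columns item, r, p,
    band (strong |r| > .7, moderate |r| > .5, weak otherwise).
    """
    if len(responses) < 3:
        raise ValueError("need at least 3 patients")
    codes = np.array([DIAGNOSIS_ORDER[Diagnosis(d)] for d in diagnoses])
    if len(codes) != len(responses):
        raise ValueError("responses and diagnoses must be parallel")
    rows = []
    for item in responses.columns:
        x = responses[item].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(codes == codes[0]):
            rows.append({"item": item, "r": np.nan, "p": np.nan, "band": "undefined"})
            continue
        r, p = stats.spearmanr(x, codes)
        band = "strong" if abs(r) > 0.7 else "moderate" if abs(r) > 0.5 else "weak"
        rows.append({"item": item, "r": float(r), "p": float(p), "band": band})
    return pd.DataFrame(rows)


def read_rater_matrix(path: str | Path) -> pd.DataFrame:
    """Read a subjects x raters CSV (first column = subject id)."""
    return pd.read_csv(path, index_col=0)
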