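"""Effect sizes and descriptive inference for the two-arm trial.

The trial's headline effect size is the standardized mean difference (SMD) of
change scores: the between-arm difference of mean (wave 4 - wave 1) changes,
divided by the pooled SD of the within-participant changes — identical in form
to Cohen's d applied to change scores.  Baseline comparisons use two-sample
t tests with cross-sectional Cohen's d, and 2x2 chi-square tests with the phi
coefficient.  Change-score correlation matrices (pairwise-complete Pearson r
with significance stars) mirror the trial's behaviour-vs-symptom analysis.

Missing-data policy: every statistic is complete-case for the quantities it
needs — a change score exists only when both endpoint waves were observed, and
correlations use pairwise deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "smd_change",
    "smd_from_summaries",
    "cohen_d_cross",
    "two_sample_t",
    "chisq_2x2",
    "phi_from_chi2",
    "change_scores",
    "change_correlations",
    "format_correlations",
    "CHANGE_VARIABLES",
]

#: variables entering the change-score correlation matrix
CHANGE_VARIABLES = (
    "diff_qids",
    "diff_lsas_v",
    "diff_lsas_p",
    "diff_bell_log2",
    "diff_custom_log2",
    "total_reward",
)


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and (n-1 denominator) SD of one arm's values."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def _pooled_sd(a: GroupSummary, b: GroupSummary) -> float:
    return math.sqrt(
        ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    )


def smd_from_summaries(exp: GroupSummary, wait: GroupSummary) -> float:
    """SMD of change scores from per-arm summaries of the changes."""
    sp = _pooled_sd(exp, wait)
    num = exp.mean - wait.mean
    if sp == 0:
        return 0.0 if num == 0 else math.copysign(math.inf, num)
    return num / sp


def smd_change(exp_changes: Sequence[float], wait_changes: Sequence[float]) -> float:
    """Standardized mean difference of change scores between arms.

    SMD = (mean change in the experimental arm - mean change in the waitlist
    arm) / pooled SD of the within-arm change scores (n-1 SDs).  A negative
    value means the experimental arm improved more when lower scores are
    better.  Degenerate zero pooled SD with unequal means yields signed
    infinity.
    """
    e = np.asarray([v for v in exp_changes if not np.isnan(v)], dtype=float)
    w = np.asarray([v for v in wait_changes if not np.isnan(v)], dtype=float)
    if len(e) < 2 or len(w) < 2:
        raise ValueError("need >= 2 complete change scores per arm")
    return smd_from_summaries(
        GroupSummary(len(e), float(e.mean()), float(e.std(ddof=1))),
        GroupSummary(len(w), float(w.mean()), float(w.std(ddof=1))),
    )


def cohen_d_cross(a: GroupSummary, b: GroupSummary, *, signed: bool = False) -> float:
    """Cross-sectional Cohen's d between two groups from their summaries.

    Reported unsigned by default (baseline-comparison convention); pass
    ``signed=True`` for the signed version (a minus b).
    """
    sp = _pooled_sd(a, b)
    num = a.mean - b.mean
    if sp == 0:
        return 0.0 if num == 0 else math.copysign(math.inf, num)
    d = num / sp
    return d if signed else abs(d)


class TTestResult(NamedTuple):
    t: float
    df: float
    pvalue: float


def two_sample_t(a_values, b_values, *, welch: bool = False) -> TTestResult:
    """Independent-samples t test (pooled-variance, or Welch when ``welch=True``)."""
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return TTestResult(t=float(res.statistic), df=float(res.df), pvalue=float(res.pvalue))


class Chi2Result(NamedTuple):
    chi2: float
    df: int
    pvalue: float
    phi: float


def phi_from_chi2(chi2: float, n: int) -> float:
    """Phi coefficient for a 2x2 table: sqrt(chi2 / N)."""
    if n <= 0 or chi2 < 0:
        raise ValueError("need chi2 >= 0 and N > 0")
    return math.sqrt(chi2 / n)


def chisq_2x2(table, *, yates: bool = False) -> Chi2Result:
    """Pearson chi-square test on a 2x2 count table with the phi effect size.

    Uncorrected by default; ``yates=True`` applies the continuity correction.
    phi = sqrt(chi2 / N) so phi^2 * N = chi2 exactly on the uncorrected path.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if t.sum() <= 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=yates)
    return Chi2Result(float(chi2), int(df), float(p), phi_from_chi2(float(chi2), int(t.sum())))


def change_scores(wide: pd.DataFrame) -> pd.DataFrame:
    """Per-participant wave-4 minus wave-1 change scores from a wide trial table.

    Columns produced: ``diff_qids``, ``diff_lsas_v``, ``diff_lsas_p``,
    ``diff_bell_log2``, ``diff_custom_log2`` plus carried-over ``arm`` and
    ``total_reward``.  A change is missing whenever either endpoint is missing;
    behaviour counts are log2(count+1)-transformed before differencing.
    """
    out = pd.DataFrame(index=wide.index)
    out["arm"] = wide["arm"]
    for stem, col in (("qids", "diff_qids"), ("lsas_v", "diff_lsas_v"), ("lsas_p", "diff_lsas_p")):
        out[col] = wide[f"{stem}_w4"] - wide[f"{stem}_w1"]
    for stem, col in (("bell", "diff_bell_log2"), ("custom", "diff_custom_log2")):
        out[col] = np.log2(wide[f"{stem}_w4"] + 1.0) - np.log2(wide[f"{stem}_w1"] + 1.0)
    out["total_reward"] = wide["bonus_months"] if "bonus_months" in wide else np.nan
    return out


class CorrelationMatrix(NamedTuple):
    r: pd.DataFrame
    pvalue: pd.DataFrame
    n: pd.DataFrame


def change_correlations(
    wide: pd.DataFrame, arm: str, variables: Sequence[str] = CHANGE_VARIABLES,
    *, min_pairs: int = 3,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations among change scores within one arm.

    Returns r, two-sided p and the pair count per cell; cells with fewer than
    ``min_pairs`` complete pairs are NaN.  The matrix is symmetric with a unit
    diagonal.
    """
    ch = change_scores(wide)
    sub = ch.loc[ch["arm"] == arm, list(variables)]
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.empty((k, k), dtype=int)
    np.fill_diagonal(n, sub.notna().sum().to_numpy())
    for i in range(k):
        for j in range(i + 1, k):
            pair = sub.iloc[:, [i, j]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < min_pairs or pair.iloc[:, 0].nunique() < 2 or pair.iloc[:, 1].nunique() < 2:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    idx = list(variables)
    return CorrelationMatrix(
        pd.DataFrame(r, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
        pd.DataFrame(n, index=idx, columns=idx),
    )


def format_correlations(corr: CorrelationMatrix, decimals: int = 2) -> pd.DataFrame:
    """Render an r matrix with significance stars (* p<.05, ** p<.01)."""
    def cell(r, p):
        if np.isnan(r):
            return ""
        stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
        return f"{r:.{decimals}f}{stars}"

    data = [
        [cell(corr.r.iat[i, j], corr.pvalue.iat[i, j]) for j in range(corr.r.shape[1])]
        for i in range(corr.r.shape[0])
    ]
    return pd.DataFrame(data, index=corr.r.index, columns=corr.r.columns)
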