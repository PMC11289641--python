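"""Group-wise distributional comparisons: Wilcoxon rank-sum tests, ECDFs,
Benjamini-Hochberg FDR adjustment, and quartile/boxplot summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparison",
    "wilcoxon_rank_sum",
    "ecdf",
    "bh_fdr",
    "group_summary",
    "compare_groups",
]

EXACT_MAX_PRODUCT = 10_000  # exact null up to n_a * n_b of this size, tie-free


@dataclass(frozen=True)
class GroupSummary:
    """Boxplot-style five-number summary of one group."""

    n: int
    q1: float
    median: float
    q3: float
    whisker_lo: float
    whisker_hi: float


@dataclass(frozen=True)
class GroupComparison:
    """Two-group Wilcoxon comparison with per-group summaries."""

    label_a: str
    label_b: str
    statistic: float
    pvalue: float
    summary_a: GroupSummary
    summary_b: GroupSummary


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney U) test.

    Average ranks for ties. The exact null distribution is used for small
    tie-free samples (n_a * n_b <= 10^4); otherwise the normal approximation
    with tie correction and continuity correction. Returns (U statistic of
    sample a, p-value).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= EXACT_MAX_PRODUCT and not has_ties) else "asymptotic"
    res = _stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def ecdf(values):
    """Right-continuous empirical CDF F(x) = #{v <= x} / n.

    Returns a callable evaluable at scalars or arrays.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("cannot build an ECDF from an empty sample")
    n = v.size

    def F(x):
        out = np.searchsorted(v, np.asarray(x, dtype=float), side="right") / n
        return float(out) if np.isscalar(x) else out

    return F


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, clipped to 1 and
    returned in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def group_summary(values) -> GroupSummary:
    """Q1/median/Q3 (linear-interpolation quantiles) with whiskers at
    Q1 - 1.5*IQR and Q3 + 1.5*IQR, clipped to the observed data range."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty group")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    return GroupSummary(
        n=int(v.size),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_lo=float(max(v.min(), q1 - 1.5 * iqr)),
        whisker_hi=float(min(v.max(), q3 + 1.5 * iqr)),
    )


def compare_groups(a, b, label_a: str = "a", label_b: str = "b") -> GroupComparison:
    """Wilcoxon rank-sum comparison of two groups plus boxplot summaries."""
    stat, p = wilcoxon_rank_sum(a, b)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        statistic=stat,
        pvalue=p,
        summary_a=group_summary(a),
        summary_b=group_summary(b),
    )


def compare_many(groups: dict[str, "pd.Series | np.ndarray"], reference: str) -> pd.DataFrame:
    """Each group against a reference group, with BH-adjusted q-values."""
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not among groups")
    ref = groups[reference]
    rows = []
    for name, vals in groups.items():
        if name == reference or len(vals) == 0:
            continue
        stat, p = wilcoxon_rank_sum(vals, ref)
        s = group_summary(vals)
        rows.append(
            {"group": name, "n": s.n, "median": s.median, "q1": s.q1, "q3": s.q3,
             "statistic": stat, "pvalue": p}
        )
    out = pd.DataFrame(rows).set_index("group")
    if len(out):
        out["qvalue"] = bh_fdr(out["pvalue"].to_numpy())
    return out
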