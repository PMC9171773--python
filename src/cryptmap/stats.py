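"""Group comparison statistics and summary helpers.

Wilcoxon rank-sum tests (exact for small untied samples, tie- and
continuity-corrected normal approximation otherwise), Benjamini–Hochberg
step-up FDR control, box-plot summaries, and absolute family abundance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sstats

__all__ = [
    "GroupComparison",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "box_summary",
    "absolute_family_abundance",
    "compare_groups",
]


@dataclass
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    median_a: float
    median_b: float
    rejected: bool | None = None
    p_adjusted: float | None = None


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank-sum statistic of the first sample
    (midranks under ties). The null distribution is enumerated exactly when
    both samples have n <= 10 and the pooled data are tie-free; otherwise a
    normal approximation with tie correction and continuity correction is
    used.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(x) <= 10) and (len(y) <= 10) and not has_ties
    res = _sstats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    w = float(res.statistic + len(x) * (len(x) + 1) / 2)  # U1 -> rank sum of x
    return w, float(res.pvalue)


def bh_adjust(p_values, fdr: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up procedure.

    Returns (reject flags, adjusted p-values). Flags are monotone: if a
    p-value is rejected, every smaller one is too.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < fdr < 1:
        raise ValueError("fdr must lie in (0, 1)")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = (np.arange(1, m + 1) / m) * fdr
    passing = np.flatnonzero(ranked <= thresh)
    reject = np.zeros(m, dtype=bool)
    if len(passing):
        reject[order[: passing[-1] + 1]] = True
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.clip(adj, 0.0, 1.0)
    return reject, adjusted


def box_summary(values) -> dict:
    """Box-plot summary: quartiles, whisker ends, outliers.

    Quartiles use linear interpolation; outliers lie beyond
    Q1 - 1.5 IQR or Q3 + 1.5 IQR and whiskers stop at the most extreme
    non-outlier values.
    """
    v = np.asarray(values, dtype=float).ravel()
    if len(v) == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inliers.min()),
        "whisker_high": float(inliers.max()),
        "outliers": outliers.tolist(),
    }


def absolute_family_abundance(
    table: pd.DataFrame, family_columns: list[str] | None = None
) -> pd.DataFrame:
    """Total load × per-family proportions -> absolute family abundance.

    ``table`` must contain a ``total`` column and per-family proportion
    columns ``prop_<family>`` (or pass explicit ``family_columns`` of
    proportions). Proportions must sum to <= 1 per sample; an ``Other``
    bucket absorbs any remainder. Raw zeros are preserved; the log-display
    columns substitute 1 for 0 so logarithms exist, as a display transform
    only.
    """
    if "total" not in table.columns:
        raise ValueError("table must contain a 'total' column")
    if family_columns is None:
        family_columns = [c for c in table.columns if c.startswith("prop_")]
    props = table[family_columns].to_numpy(dtype=float)
    if np.any(props < 0) or np.any(props > 1):
        raise ValueError("proportions must lie in [0, 1]")
    sums = props.sum(axis=1)
    if np.any(sums > 1 + 1e-9):
        raise ValueError("per-sample proportions sum to more than 1")
    total = table["total"].to_numpy(dtype=float)
    if np.any(total < 0):
        raise ValueError("totals must be non-negative")
    out = table.copy()
    for col in family_columns:
        fam = col.removeprefix("prop_")
        abund = total * table[col].to_numpy(dtype=float)
        out[f"abs_{fam}"] = abund
        out[f"abs_{fam}_logdisplay"] = np.where(abund == 0, 1.0, abund)
    other = total * (1.0 - sums)
    out["abs_Other"] = other
    out["abs_Other_logdisplay"] = np.where(other == 0, 1.0, other)
    return out


def compare_groups(
    records: pd.DataFrame,
    metrics: list[str],
    group_column: str = "condition",
    group_a: str | None = None,
    group_b: str | None = None,
    fdr: float = 0.1,
) -> pd.DataFrame:
    """Rank-sum comparison of every metric between two groups, BH-corrected.

    NaN metric values (e.g., undefined depths in empty crypts) are dropped
    per metric.
    """
    groups = sorted(records[group_column].unique())
    if group_a is None or group_b is None:
        if len(groups) != 2:
            raise ValueError(
                f"need exactly 2 groups or explicit labels; found {groups}"
            )
        group_a, group_b = groups
    rows: list[GroupComparison] = []
    for metric in metrics:
        a = records.loc[records[group_column] == group_a, metric].dropna().to_numpy()
        b = records.loc[records[group_column] == group_b, metric].dropna().to_numpy()
        stat, p = wilcoxon_rank_sum(a, b)
        rows.append(
            GroupComparison(
                metric=metric, group_a=group_a, group_b=group_b,
                n_a=len(a), n_b=len(b), statistic=stat, p_value=p,
                median_a=float(np.median(a)), median_b=float(np.median(b)),
            )
        )
    reject, adjusted = bh_adjust([r.p_value for r in rows], fdr=fdr)
    for r, rej, adj in zip(rows, reject, adjusted):
        r.rejected = bool(rej)
        r.p_adjusted = float(adj)
    return pd.DataFrame([r.__dict__ for r in rows])
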