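"""Group comparisons and correlation structure of cohort features.

Two-group contrasts use the unpaired two-tailed Mann-Whitney U test (exact
null distribution for small tie-free samples, normal approximation with tie
correction otherwise). Feature-feature association uses Spearman rank
correlation on pairwise-complete observations, annotated with the usual
significance stars. No multiple-testing correction is applied by default;
Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

_EXACT_MAX_PRODUCT = 400  # exact U distribution when n1*n2 <= this and no ties


@dataclass(frozen=True)
class GroupComparison:
    """One Mann-Whitney contrast between two groups on one feature."""

    feature: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float  # U of group_a
    p_value: float
    median_a: float
    median_b: float
    method: str  # "exact" or "asymptotic"


@dataclass
class CorrelationMatrix:
    """Spearman rho, p-values and star annotations for a feature set."""

    features: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    feature: str = "",
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-tailed unpaired Mann-Whitney U test.

    Missing values are dropped within each vector. The exact permutation
    distribution is used when n1·n2 ≤ 400 and there are no ties; otherwise
    the normal approximation with tie correction (and continuity correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("a and b must each contain at least one non-missing value")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = len(a) * len(b) <= _EXACT_MAX_PRODUCT and not has_ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    pvalue = float(res.pvalue)
    if res.statistic == len(a) * len(b) / 2:
        pvalue = 1.0  # U at its null mean: two-tailed p is 1 by symmetry
    return GroupComparison(
        feature=feature,
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        u_statistic=float(res.statistic),
        p_value=min(pvalue, 1.0),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        method="exact" if exact else "asymptotic",
    )


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def spearman_matrix(
    table: pd.DataFrame, features: Sequence[str], min_pairs: int = 3
) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlation matrix with significance stars.

    Rho uses average ranks (midranks for ties). Pairs with fewer than
    ``min_pairs`` complete observations, or involving a constant feature,
    get NaN (flagged, not zero). Stars: * p<0.05, ** p<0.01, *** p<0.001.
    """
    features = list(features)
    k = len(features)
    rho = np.full((k, k), np.nan)
    pmat = np.full((k, k), np.nan)
    np.fill_diagonal(rho, 1.0)
    for i, j in combinations(range(k), 2):
        x = table[features[i]].to_numpy(dtype=float)
        y = table[features[j]].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < min_pairs:
            continue
        xs, ys = x[ok], y[ok]
        if np.all(xs == xs[0]) or np.all(ys == ys[0]):
            continue  # constant feature: correlation undefined
        r, p = sps.spearmanr(xs, ys)
        rho[i, j] = rho[j, i] = r
        pmat[i, j] = pmat[j, i] = p
    rho_df = pd.DataFrame(rho, index=features, columns=features)
    p_df = pd.DataFrame(pmat, index=features, columns=features)
    stars_df = p_df.map(_stars)
    return CorrelationMatrix(features, rho_df, p_df, stars_df)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; off by default in summaries)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    prev = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        prev = min(prev, p[i] * n / (rank_idx + 1))
        adj[i] = prev
    return adj


def group_summary(
    table: pd.DataFrame,
    group_col: str,
    features: Sequence[str],
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Per-group medians/IQRs plus all pairwise Mann-Whitney contrasts.

    Returns ``(summary, comparisons)``; ``summary`` has one row per
    (feature, group) with n, median, q1, q3. Adjusted p-values, if wanted,
    come from :func:`comparisons_frame` with ``adjust=True``.
    """
    if group_col not in table.columns:
        raise KeyError(f"unknown grouping column {group_col!r}")
    levels = [g for g in table[group_col].dropna().unique()]
    if len(levels) < 2:
        raise ValueError("grouping must have at least two nonempty levels")
    rows = []
    for feat in features:
        for level in levels:
            vals = table.loc[table[group_col] == level, feat].dropna()
            rows.append(
                {
                    "feature": feat,
                    "group": level,
                    "n": len(vals),
                    "median": vals.median() if len(vals) else np.nan,
                    "q1": vals.quantile(0.25) if len(vals) else np.nan,
                    "q3": vals.quantile(0.75) if len(vals) else np.nan,
                }
            )
    comparisons = []
    for feat in features:
        for ga, gb in combinations(levels, 2):
            va = table.loc[table[group_col] == ga, feat].to_numpy(dtype=float)
            vb = table.loc[table[group_col] == gb, feat].to_numpy(dtype=float)
            comparisons.append(mann_whitney(va, vb, feature=feat, group_a=ga, group_b=gb))
    return pd.DataFrame(rows), comparisons


def comparisons_frame(comparisons: list[GroupComparison], adjust: bool = False) -> pd.DataFrame:
    """Tabulate contrasts; optionally append BH-adjusted p-values."""
    df = pd.DataFrame([c.__dict__ for c in comparisons])
    if adjust and len(df):
        df["p_adjusted"] = benjamini_hochberg(df["p_value"].to_numpy())
    return df
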