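"""Rank-based group comparisons for dyadic overlap and intensity data.

Implements the Mann-Whitney U test (exact enumeration for small samples,
tie-corrected normal approximation otherwise), the tie-corrected
Kruskal-Wallis H test, and Nemenyi-type all-pairs comparisons on mean
ranks using the studentized-range reference — the combination of tests a
rank-sum analysis of overlap percentages and kernel intensities calls for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RankTestResult",
    "summarize",
    "mann_whitney",
    "kruskal_wallis",
    "pairwise_tukey_on_ranks",
    "EXACT_PRODUCT_CUTOFF",
]

#: exact enumeration is used when n1*n2 is at or below this product
EXACT_PRODUCT_CUTOFF = 20


@dataclass
class RankTestResult:
    """Result of a rank-sum test, in the reporting style 'U = ..; P = ..'."""

    method: str
    p_value: float
    statistic_U: float | None = None
    statistic_T: float | None = None
    statistic_H: float | None = None
    df: int | None = None
    tie_corrected: bool = False
    exact: bool = False
    n_per_group: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")

    def __str__(self) -> str:
        parts = []
        if self.statistic_U is not None:
            parts.append(f"U = {self.statistic_U:g}")
        if self.statistic_T is not None:
            parts.append(f"T = {self.statistic_T:g}")
        if self.statistic_H is not None:
            parts.append(f"H = {self.statistic_H:g}")
        if self.df is not None:
            parts.append(f"df = {self.df}")
        parts.append(
            "P < 0.001" if self.p_value < 0.001 else f"P = {self.p_value:.3f}"
        )
        return f"{self.method}: " + "; ".join(parts)


def summarize(values) -> dict:
    """Mean, median, SD (n-1), range and n of a numeric vector.

    SD is reported as NaN (not zero) for a single observation.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty vector")
    if not np.isfinite(v).all():
        raise ValueError("non-finite values in summary input")
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "median": float(np.median(v)),
        "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
        "min": float(v.min()),
        "max": float(v.max()),
    }


def _u_from_ranks(pooled_ranks: np.ndarray, idx_a: np.ndarray, n1: int, n2: int) -> float:
    r1 = pooled_ranks[idx_a].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


def mann_whitney(a, b) -> RankTestResult:
    """Two-sided Mann-Whitney rank-sum test.

    U is reported for the first group; T is the rank sum of the smaller
    group (first group on a size tie).  For n1*n2 <= 20 the p-value is an
    exact enumeration over all C(n1+n2, n1) group labellings of the pooled
    midranks; otherwise a tie-corrected normal approximation with
    continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    if not np.isfinite(pooled).all():
        raise ValueError("non-finite values")
    ranks = sps.rankdata(pooled)  # midranks
    idx_a = np.arange(n1)
    u_obs = _u_from_ranks(ranks, idx_a, n1, n2)
    r1 = float(ranks[:n1].sum())
    r2 = float(ranks[n1:].sum())
    t_stat = r1 if n1 <= n2 else r2

    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if n1 * n2 <= EXACT_PRODUCT_CUTOFF:
        n = n1 + n2
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        for comb in combinations(range(n), n1):
            u = _u_from_ranks(ranks, np.asarray(comb), n1, n2)
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        p = hits / total
        return RankTestResult(
            "Mann-Whitney Rank Sum Test", p, statistic_U=u_obs,
            statistic_T=t_stat, tie_corrected=has_ties, exact=True,
            n_per_group=(n1, n2),
        )

    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all values identical
        return RankTestResult(
            "Mann-Whitney Rank Sum Test", 1.0, statistic_U=u_obs,
            statistic_T=t_stat, tie_corrected=True, exact=False,
            n_per_group=(n1, n2),
        )
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * sps.norm.sf(z))
    return RankTestResult(
        "Mann-Whitney Rank Sum Test", p, statistic_U=u_obs,
        statistic_T=t_stat, tie_corrected=has_ties, exact=False,
        n_per_group=(n1, n2),
    )


def _tie_correction(pooled: np.ndarray) -> float:
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    return 1.0 - float((counts**3 - counts).sum()) / (n**3 - n)


def kruskal_wallis(groups) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H test across k groups (df = k-1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(groups)
    if not np.isfinite(pooled).all():
        raise ValueError("non-finite values")
    n = pooled.size
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size].sum()
        h += r * r / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    corr = _tie_correction(pooled)
    if corr <= 0:  # every pooled value identical
        h_corr = 0.0
    else:
        h_corr = h / corr
    df = len(groups) - 1
    p = float(sps.chi2.sf(h_corr, df)) if h_corr > 0 else 1.0
    return RankTestResult(
        "Kruskal-Wallis ANOVA on ranks", max(p, np.finfo(float).tiny),
        statistic_H=float(h_corr), df=df, tie_corrected=corr < 1.0,
        n_per_group=tuple(g.size for g in groups),
    )


def pairwise_tukey_on_ranks(groups, labels=None, alpha: float = 0.05) -> pd.DataFrame:
    """Nemenyi-type all-pairs mean-rank comparisons (Tukey-style).

    For groups i, j the statistic
    q = |Rbar_i - Rbar_j| / sqrt(C * N(N+1)/12 * (1/n_i + 1/n_j) / 2)
    is referred to the studentized range distribution with k groups and
    infinite df; C is the tie-correction factor.  Returns a table with
    adjusted p-values and a significance flag at ``alpha``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group needs at least one value")
    k = len(groups)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    corr = _tie_correction(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        start += g.size
    rows = []
    base_var = n * (n + 1) / 12.0 * (corr if corr > 0 else 1.0)
    for i, j in combinations(range(k), 2):
        ni, nj = groups[i].size, groups[j].size
        se = math.sqrt(base_var * (1.0 / ni + 1.0 / nj) / 2.0)
        diff = abs(mean_ranks[i] - mean_ranks[j])
        q = diff / se if se > 0 else 0.0
        p_adj = float(sps.studentized_range.sf(q, k, np.inf)) if q > 0 else 1.0
        p_adj = min(1.0, p_adj)
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_rank_a": mean_ranks[i],
                "mean_rank_b": mean_ranks[j],
                "q": q,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)
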