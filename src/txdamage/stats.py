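"""Rank-based statistics for stratified group comparisons.

Pairwise comparisons between gene bins use the two-sided Mann-Whitney
rank-sum test (exact enumeration when both groups are small, otherwise the
normal approximation with tie and continuity correction), with Bonferroni
correction over the number of pairs. A one-sample signed-rank-versus-zero
mode is provided for within-group location tests.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.stats as ss

_EXACT_MW_MAX_N = 8
_EXACT_SPEARMAN_MAX_N = 9


@dataclass(frozen=True)
class PairResult:
    group_a: str
    group_b: str
    u_statistic: float
    p_raw: float
    p_adj: float
    method: str


@dataclass(frozen=True)
class GroupSummary:
    n: int
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class GroupComparison:
    groups: dict
    pairs: tuple


def bonferroni(pvals: Sequence[float]) -> list:
    """p_adj = min(1, p * m)."""
    arr = np.asarray(pvals, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    return np.minimum(1.0, arr * m).tolist()


def _u_statistic(ranks: np.ndarray, idx: Sequence[int], n1: int) -> float:
    return float(sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2.0)


def _mann_whitney_exact(a: np.ndarray, b: np.ndarray):
    """Two-sided exact rank-sum p by full enumeration on midranks.

    p = min(1, 2 * min(P(U <= u), P(U >= u))), which handles ties exactly.
    """
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = ss.rankdata(pooled)
    u_obs = _u_statistic(ranks, range(n1), n1)
    count_le = count_ge = total = 0
    eps = 1e-9
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = _u_statistic(ranks, idx, n1)
        total += 1
        if u <= u_obs + eps:
            count_le += 1
        if u >= u_obs - eps:
            count_ge += 1
    p = min(1.0, 2.0 * min(count_le, count_ge) / total)
    return u_obs, p


def mann_whitney(a, b):
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both groups have <= 8 observations; otherwise the
    normal approximation with tie and continuity correction.

    Returns (U, p, method).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("groups must be non-empty")
    if a.size <= _EXACT_MW_MAX_N and b.size <= _EXACT_MW_MAX_N:
        u, p = _mann_whitney_exact(a, b)
        return u, p, "exact"
    res = ss.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), "asymptotic"


def rank_compare(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """All pairwise two-sided rank-sum tests with Bonferroni correction.

    `groups` maps label -> values; at least 2 non-empty groups are required.
    Group summaries report the median and quartiles (boxplot statistics).
    """
    if len(groups) < 2:
        raise ValueError("rank_compare requires at least 2 groups")
    arrays = {}
    summaries = {}
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {label!r} is empty")
        arrays[label] = arr
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        summaries[label] = GroupSummary(n=int(arr.size), median=float(med), q1=float(q1), q3=float(q3))
    labels = list(arrays)
    raw = []
    for la, lb in itertools.combinations(labels, 2):
        u, p, method = mann_whitney(arrays[la], arrays[lb])
        raw.append((la, lb, u, p, method))
    adj = bonferroni([r[3] for r in raw])
    pairs = tuple(
        PairResult(la, lb, u, p, p_adj, method)
        for (la, lb, u, p, method), p_adj in zip(raw, adj)
    )
    return GroupComparison(groups=summaries, pairs=pairs)


def signed_rank_vs_zero(values):
    """One-sample Wilcoxon signed-rank test of median == 0 (two-sided)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one value")
    res = ss.wilcoxon(arr, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p over all orderings of the y ranks."""
    n = rx.size
    perms = np.array(list(itertools.permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - ry.mean()
    denom = np.sqrt((rxc**2).sum()) * np.sqrt((pc**2).sum(axis=1))
    rhos = pc @ rxc / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x, y):
    """Tie-corrected Spearman rank correlation with two-sided p.

    The p-value uses the large-sample t approximation, replaced by an exact
    permutation enumeration for n <= 9.

    Raises
    ------
    ValueError
        On length mismatch, n < 3, non-finite values, or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("spearman requires n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("spearman requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined: zero variance")
    rx = ss.rankdata(x)
    ry = ss.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if x.size <= _EXACT_SPEARMAN_MAX_N:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        p = float(ss.spearmanr(x, y).pvalue)
    return rho, p


def significance_stars(p: float) -> str:
    """Map a p-value to the star annotation used in group-comparison figures."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
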