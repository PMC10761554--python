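"""Differential-expression classification and cross-condition consistency.

Genes are called up/down per condition with strict thresholds (|log2FC| >
0.7, padj < 0.05 by default), then scored for how many of the cell-type x
agent conditions they are up-regulated in. A minimal negative-binomial Wald
test is included so the synthetic pipeline runs end-to-end; it is plumbing,
not a replacement for a full DE framework.
"""
from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as ss
from statsmodels.stats.multitest import multipletests

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "ns"
STATUS_MISSING = "missing"

DEFAULT_LFC_THRESHOLD = 0.7
DEFAULT_ALPHA = 0.05

_MIN_DISPERSION = 1e-8


def classify_deg(
    log2fc: float,
    padj: float | None,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> str:
    """Status of one gene in one condition: "up", "down", or "ns".

    Strict inequalities at both thresholds; a missing padj yields "ns".
    """
    if log2fc is None or not math.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    if padj is None or (isinstance(padj, float) and math.isnan(padj)):
        return STATUS_NS
    if padj < alpha and log2fc > lfc_threshold:
        return STATUS_UP
    if padj < alpha and log2fc < -lfc_threshold:
        return STATUS_DOWN
    return STATUS_NS


def build_status_grid(
    tables: Mapping[str, pd.DataFrame],
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    absent_as: str = STATUS_NS,
) -> pd.DataFrame:
    """Genes x conditions status matrix from per-condition DE tables.

    Each table needs columns gene_id, log2fc, padj. Genes absent from a
    condition's table are filled with `absent_as` ("ns" by default, so
    consistency counts stay conservative).
    """
    all_genes = sorted(set(itertools.chain.from_iterable(t["gene_id"] for t in tables.values())))
    grid = pd.DataFrame(absent_as, index=all_genes, columns=list(tables))
    grid.index.name = "gene_id"
    for cond, table in tables.items():
        for gid, lfc, padj in zip(table["gene_id"], table["log2fc"], table["padj"]):
            p = None if pd.isna(padj) else float(padj)
            grid.loc[gid, cond] = classify_deg(float(lfc), p, lfc_threshold, alpha)
    return grid


def condition_overlap(grid: pd.DataFrame, conditions: Sequence[str]):
    """Disjoint Venn regions of up-regulated genes across three conditions.

    Returns (region_counts, triple_members): region keys are condition names
    joined with "&" (7 regions); triple_members is the sorted membership of
    the 3-way intersection.
    """
    if len(conditions) != 3:
        raise ValueError("condition_overlap requires exactly 3 conditions")
    for c in conditions:
        if c not in grid.columns:
            raise ValueError(f"condition {c!r} missing from grid")
    sets = {c: set(grid.index[grid[c] == STATUS_UP]) for c in conditions}
    regions = {}
    for r in (1, 2, 3):
        for combo in itertools.combinations(conditions, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set().union(*(sets[c] for c in conditions if c not in combo))
            regions["&".join(combo)] = len(inside - outside)
    triple = sorted(set.intersection(*sets.values()))
    return regions, triple


def consistency_sets(grid: pd.DataFrame, k_min: int):
    """Genes up-regulated in at least k_min conditions.

    Returns (df, stringent) where df has columns gene_id/up_count sorted by
    descending up-count then gene_id, and stringent lists genes up in every
    condition of the grid.
    """
    n_cond = grid.shape[1]
    if k_min > n_cond:
        raise ValueError(f"k_min={k_min} exceeds number of conditions ({n_cond})")
    up_counts = (grid == STATUS_UP).sum(axis=1)
    sel = up_counts[up_counts >= k_min]
    df = (
        pd.DataFrame({"gene_id": sel.index, "up_count": sel.values})
        .sort_values(["up_count", "gene_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
    stringent = sorted(up_counts.index[up_counts == n_cond])
    return df, stringent


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios normalization factors, one per sample (column).

    Genes containing any zero are excluded from the reference (their log
    geometric mean is -inf).
    """
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    loggeo = logc.mean(axis=1)
    usable = np.isfinite(loggeo)
    if not usable.any():
        raise ValueError("size_factors: every gene contains a zero count")
    ratios = logc[usable] - loggeo[usable, None]
    return np.exp(np.median(ratios, axis=0))


def nb_de_test(
    control: np.ndarray,
    treated: np.ndarray,
    gene_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Minimal per-gene negative-binomial Wald test.

    Median-of-ratios size factors over all samples; log2FC of normalized
    group means with a 0.5 pseudo-count; method-of-moments dispersion pooled
    within groups (floored at 1e-8); Wald z on the log scale referred to a
    t distribution with n_c + n_t - 2 df; Benjamini-Hochberg padj. All-zero
    genes get log2fc 0 and missing p.

    Returns a DataFrame with columns gene_id, base_mean, log2fc, pvalue, padj.
    """
    control = np.atleast_2d(np.asarray(control, dtype=float))
    treated = np.atleast_2d(np.asarray(treated, dtype=float))
    if control.shape[0] != treated.shape[0]:
        raise ValueError("control and treated must cover the same genes")
    n_c, n_t = control.shape[1], treated.shape[1]
    if n_c < 2 or n_t < 2:
        raise ValueError("need >= 2 replicates per group")
    if np.any(control < 0) or np.any(treated < 0):
        raise ValueError("counts must be non-negative")
    n_genes = control.shape[0]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]

    counts = np.hstack([control, treated])
    sf = size_factors(counts)
    norm = counts / sf
    nc, nt = norm[:, :n_c], norm[:, n_c:]
    mu_c, mu_t = nc.mean(axis=1), nt.mean(axis=1)
    log2fc = np.log2((mu_t + 0.5) / (mu_c + 0.5))

    var_c = nc.var(axis=1, ddof=1)
    var_t = nt.var(axis=1, ddof=1)
    pooled_var = ((n_c - 1) * var_c + (n_t - 1) * var_t) / (n_c + n_t - 2)
    mu_pool = (n_c * mu_c + n_t * mu_t) / (n_c + n_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mu_pool) / mu_pool**2
    alpha = np.where(np.isfinite(alpha), alpha, _MIN_DISPERSION)
    alpha = np.maximum(alpha, _MIN_DISPERSION)

    # delta-method variance of log(mean) per group, NB variance mu + alpha*mu^2
    se_ln = np.sqrt(
        (1.0 / np.maximum(mu_c, 0.5) + alpha) / n_c
        + (1.0 / np.maximum(mu_t, 0.5) + alpha) / n_t
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc * np.log(2.0) / se_ln
    pvalue = 2.0 * ss.t.sf(np.abs(z), df=n_c + n_t - 2)

    all_zero = counts.sum(axis=1) == 0
    log2fc = np.where(all_zero, 0.0, log2fc)
    pvalue = np.where(all_zero, np.nan, pvalue)

    padj = np.full(n_genes, np.nan)
    tested = np.isfinite(pvalue)
    if tested.any():
        padj[tested] = multipletests(pvalue[tested], method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "base_mean": norm.mean(axis=1),
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
        }
    )
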