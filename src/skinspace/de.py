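"""Pairwise differential expression between bin groups.

Per gene, groups are compared with the two-sided Wilcoxon rank-sum
(Mann-Whitney) test on normalized expression: exact by enumeration for
tiny tie-free samples (n1 + n2 <= 10), otherwise the tie- and
continuity-corrected normal approximation. Genes enter testing when
detected in at least ``min_pct`` of either group and when the absolute
log2 fold change clears ``logfc_threshold``; mitochondrial (``MT-``)
genes are excluded. P-values are adjusted by Benjamini-Hochberg by
default (Bonferroni optional) over the tested genes only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import NormalizedMatrix

LOGFC_EPS = 1e-9
EXACT_MAX_N = 10


@dataclass
class DERecord:
    gene: str
    p_value: float
    p_adjusted: float
    log2_fc: float
    pct_1: float
    pct_2: float
    n_1: int
    n_2: int


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p by full enumeration of rank assignments (no ties)."""
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w_obs = ranks[:n1].sum()
    all_ranks = range(1, n1 + n2 + 1)
    sums = np.array([sum(c) for c in combinations(all_ranks, n1)])
    total = comb(n1 + n2, n1)
    p_low = (sums <= w_obs).sum() / total
    p_high = (sums >= w_obs).sum() / total
    return min(1.0, 2.0 * min(p_low, p_high))


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided rank-sum test; returns (U statistic of x, p-value).

    Exact enumeration when n1 + n2 <= 10 and there are no ties;
    otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1 = x.size
    u_stat = float(
        stats.rankdata(np.concatenate([x, y]))[:n1].sum() - n1 * (n1 + 1) / 2
    )
    combined = np.concatenate([x, y])
    tie_free = len(np.unique(combined)) == combined.size
    if combined.size <= EXACT_MAX_N and tie_free:
        return u_stat, _exact_rank_sum_p(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return u_stat, float(res.pvalue)


def bh_adjust(p_values, method: str = "BH") -> np.ndarray:
    """Step-up Benjamini-Hochberg (or Bonferroni) adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]


def log2_fold_change(x: np.ndarray, y: np.ndarray, eps: float = LOGFC_EPS) -> float:
    """log2 of the ratio of de-logged group means with a small pseudo-count."""
    return float(np.log2((np.expm1(x).mean() + eps) / (np.expm1(y).mean() + eps)))


def find_markers(
    norm: NormalizedMatrix,
    group_labels,
    group_1: str,
    group_2: str,
    min_pct: float = 0.01,
    logfc_threshold: float = 0.0,
    only_pos: bool = False,
    mt_prefix: str = "MT-",
    p_adjust: str = "BH",
) -> pd.DataFrame:
    """Per-gene DE table between two bin groups.

    Returns rows only for tested genes, sorted by p-value then gene
    name; BH adjustment spans the tested genes only.
    """
    labels = np.asarray(group_labels)
    if len(labels) != norm.n_bins:
        raise ValueError("group_labels length does not match number of bins")
    mask1 = labels == group_1
    mask2 = labels == group_2
    if not mask1.any():
        raise ValueError(f"unknown or empty group label {group_1!r}")
    if not mask2.any():
        raise ValueError(f"unknown or empty group label {group_2!r}")
    if (mask1 & mask2).any():
        raise ValueError("groups overlap")

    keep_gene = ~np.array([str(g).startswith(mt_prefix) for g in norm.gene_names])
    records = []
    mat = norm.matrix
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    for gi in np.flatnonzero(keep_gene):
        row = np.asarray(mat.getrow(gi).todense()).ravel()
        x, y = row[mask1], row[mask2]
        pct1 = float((x > 0).mean())
        pct2 = float((y > 0).mean())
        if max(pct1, pct2) < min_pct:
            continue
        lfc = log2_fold_change(x, y)
        if abs(lfc) < logfc_threshold:
            continue
        if only_pos and lfc <= 0:
            continue
        _, p = rank_sum_test(x, y)
        records.append(
            {
                "gene": norm.gene_names[gi],
                "p_value": p,
                "log2_fc": lfc,
                "pct_1": pct1,
                "pct_2": pct2,
                "n_1": n1,
                "n_2": n2,
            }
        )
    table = pd.DataFrame(
        records,
        columns=["gene", "p_value", "log2_fc", "pct_1", "pct_2", "n_1", "n_2"],
    )
    if len(table):
        table["p_adjusted"] = bh_adjust(table["p_value"].to_numpy(), method=p_adjust)
    else:
        table["p_adjusted"] = np.array([], dtype=float)
    table = table.sort_values(["p_value", "gene"], kind="mergesort").reset_index(
        drop=True
    )
    return table.loc[
        :, ["gene", "p_value", "p_adjusted", "log2_fc", "pct_1", "pct_2", "n_1", "n_2"]
    ]
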