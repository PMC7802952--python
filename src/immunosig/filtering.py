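"""Wilcoxon rank-sum pre-filtering of genes.

Before any model fitting, every gene is screened for differential
expression between the worst-prognosis immune cluster (B) and the pooled
remaining samples, with a deliberately permissive threshold (p <= 0.1 by
default) so that the downstream backward elimination starts from a broad
candidate pool.  The plug-in estimate ``alpha * m / k`` quantifies the
false discovery rate implied by keeping ``k`` of ``m`` genes at level
``alpha`` (assuming all nulls, pi0 = 1).

The rank-sum p-value switches between exact enumeration of rank splits
(combined n < 20) and the tie-corrected normal approximation with
continuity correction (combined n >= 20).  Both routes are implemented
here rather than delegated, so that library implementations can serve as
independent cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FilterResult", "wrs_pvalue", "filter_genes", "fdr_estimate"]

_EXACT_MAX_N = 20  # combined sample size below which the exact null is enumerated


@dataclass
class FilterResult:
    """Outcome of the rank-sum pre-filter over a gene universe."""

    passing_genes: list[str]
    pvalues: pd.Series
    alpha: float
    m_total: int
    k_passing: int
    fdr: float | None

    def __post_init__(self):
        assert self.k_passing == len(self.passing_genes)


def wrs_pvalue(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Mid-ranks are used for ties.  For combined n below 20 the null
    distribution of the rank sum is enumerated exhaustively over all
    C(n, n_x) group assignments; at or above 20 a normal approximation
    with tie-corrected variance and a 0.5 continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wrs_pvalue requires two non-empty samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    n, nx = pooled.size, x.size
    ranks = stats.rankdata(pooled)  # mid-ranks
    w_obs = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0

    if n < _EXACT_MAX_N:
        dev = abs(w_obs - mu)
        count = 0
        total = 0
        for idx in combinations(range(n), nx):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
                count += 1
        return count / total

    # tie-corrected variance of the rank sum
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = nx * (n - nx) / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(w_obs - mu) - 0.5) / np.sqrt(var)  # continuity correction
    return float(2.0 * stats.norm.sf(max(z, 0.0)))


def filter_genes(expr: pd.DataFrame, cluster_labels, alpha: float = 0.1) -> FilterResult:
    """Keep genes differentially expressed in Cluster B vs the rest.

    Parameters
    ----------
    expr
        Genes x samples expression matrix (columns are sample IDs).
    cluster_labels
        Per-sample A/B/C labels aligned with ``expr``'s columns.
    alpha
        Retention threshold: a gene is kept iff its p-value <= alpha.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    labels = pd.Series(np.asarray(cluster_labels), index=expr.columns)
    in_b = (labels == "B").to_numpy()
    if in_b.sum() == 0 or (~in_b).sum() == 0:
        raise ValueError("both Cluster B and not-Cluster-B must be non-empty")

    values = expr.to_numpy(dtype=float)
    pvals = np.array([wrs_pvalue(row[in_b], row[~in_b]) for row in values])
    pseries = pd.Series(pvals, index=expr.index, name="wrs_p")
    passing = list(expr.index[pvals <= alpha])  # p > alpha is filtered out
    k = len(passing)
    return FilterResult(
        passing_genes=passing,
        pvalues=pseries,
        alpha=alpha,
        m_total=expr.shape[0],
        k_passing=k,
        fdr=fdr_estimate(expr.shape[0], k, alpha) if k > 0 else None,
    )


def fdr_estimate(m_total: int, k_passing: int, alpha: float) -> float:
    """Plug-in FDR of a fixed-threshold screen: ``alpha * m / k``.

    Under a complete null, ``alpha * m`` genes pass by chance; dividing by
    the observed pass count bounds the expected false-discovery fraction.
    """
    if k_passing < 1:
        raise ValueError("fdr_estimate undefined when no genes pass")
    if m_total < k_passing:
        raise ValueError("k_passing cannot exceed m_total")
    return alpha * m_total / k_passing
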