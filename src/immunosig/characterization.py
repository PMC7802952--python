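"""Statistical characterization of prognostic classes.

Enrichment/depletion of binary annotations (e.g. somatic mutation flags)
between the good- and bad-prognosis classes via exact hypergeometric tail
sums; Benjamini-Hochberg control for gene-level screens; chi-square
independence against molecular subtype partitions; Kruskal-Wallis trend
of immune-infiltration scores across clusters; and the significance of a
gene-set intersection across repeated selection runs under a
uniform/independent null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .filtering import wrs_pvalue

__all__ = [
    "HypergeomQuery",
    "StabilityReport",
    "hypergeom_test",
    "mutation_class_test",
    "bh_discoveries",
    "symmetric_difference_de",
    "chi_square_independence",
    "kruskal_wallis",
    "intersection_significance",
    "stability_report",
]


@dataclass(frozen=True)
class HypergeomQuery:
    """Tail query on the hypergeometric distribution.

    Drawing ``n`` samples without replacement from a population of size
    ``N`` containing ``B`` marked items, ``b`` marked items are observed.
    """

    N: int
    B: int
    n: int
    b: int
    tail: Literal["upper", "lower"] = "upper"

    def __post_init__(self):
        if not (0 <= self.B <= self.N and 0 <= self.n <= self.N):
            raise ValueError("need 0 <= B <= N and 0 <= n <= N")
        if not 0 <= self.b <= min(self.B, self.n):
            raise ValueError("need 0 <= b <= min(B, n)")
        if self.tail not in ("upper", "lower"):
            raise ValueError(f"unknown tail {self.tail!r}")


def hypergeom_test(q: HypergeomQuery) -> float:
    """Exact hypergeometric tail probability, inclusive of the observed count.

    upper: P(X >= b);  lower: P(X <= b).
    """
    rv = stats.hypergeom(q.N, q.B, q.n)
    if q.tail == "upper":
        return float(rv.sf(q.b - 1))
    return float(rv.cdf(q.b))


def mutation_class_test(mutations, calls, direction: Literal["depleted", "enriched"]) -> float:
    """Hypergeometric test of a binary flag against the BPx/GPx partition.

    ``depleted`` asks whether the bad-prognosis class (BPx) carries fewer
    flagged samples than expected; ``enriched`` asks for more.
    """
    mutations = np.asarray(mutations, dtype=int)
    calls = np.asarray(calls)
    if mutations.shape != calls.shape:
        raise ValueError("mutations and calls must be aligned")
    in_bpx = calls == "BPx"
    if in_bpx.sum() == 0 or (~in_bpx).sum() == 0:
        raise ValueError("both BPx and GPx must be non-empty")
    q = HypergeomQuery(
        N=mutations.size,
        B=int(mutations.sum()),
        n=int(in_bpx.sum()),
        b=int(mutations[in_bpx].sum()),
        tail="lower" if direction == "depleted" else "upper",
    )
    return hypergeom_test(q)


def bh_discoveries(pvalues: Sequence[float], q: float) -> list[int]:
    """Indices of Benjamini-Hochberg discoveries at FDR level ``q``."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return []
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return list(np.nonzero(reject)[0])


def symmetric_difference_de(
    expr: pd.DataFrame, set1_members, set2_members, q: float = 0.05
) -> pd.DataFrame:
    """Differential expression between the two sides of a symmetric difference.

    Samples in set1-only are compared per gene (rank-sum) with samples in
    set2-only; discoveries are BH-controlled at ``q`` and returned sorted
    by p-value, as a frame with columns ``gene`` and ``p``.
    """
    set1 = np.asarray(set1_members, dtype=bool)
    set2 = np.asarray(set2_members, dtype=bool)
    only1 = set1 & ~set2
    only2 = set2 & ~set1
    if only1.sum() == 0 or only2.sum() == 0:
        raise ValueError("both difference sets must be non-empty")
    values = expr.to_numpy(dtype=float)
    pvals = np.array([wrs_pvalue(row[only1], row[only2]) for row in values])
    idx = bh_discoveries(pvals, q)
    out = pd.DataFrame({"gene": expr.index[idx], "p": pvals[idx]})
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def chi_square_independence(table) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2 x K count table.

    No continuity correction (K may exceed 2).
    """
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has an all-zero margin")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis statistic and chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):  # scipy rejects the all-identical case
        return 0.0, 1.0
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def intersection_significance(
    set_sizes: Sequence[int], universe_size: int, k_observed: int
) -> float:
    """Upper bound on the probability of a k-gene intersection by chance.

    Each of the repeated runs is modelled as drawing its reported set
    uniformly and independently from the universe, so a fixed gene lies in
    all runs with probability q = prod(size_i / universe).  The bound is
    the binomial tail P(X >= k) for X ~ Binomial(universe, q), evaluated
    in log space so that astronomically small bounds stay finite.
    """
    sizes = list(set_sizes)
    if k_observed < 0:
        raise ValueError("k_observed must be non-negative")
    if any(s < 0 or s > universe_size for s in sizes):
        raise ValueError("set sizes must lie in [0, universe_size]")
    if not sizes:
        raise ValueError("need at least one set size")
    if k_observed == 0:
        return 1.0
    if k_observed > min(sizes):
        return 0.0  # impossible: the intersection cannot exceed the smallest set
    if len(sizes) == 1:
        return 1.0  # a single run of size s >= k contains k genes with certainty

    log_q = float(np.sum(np.log(np.array(sizes) / universe_size)))
    q = np.exp(log_q)
    log1m_q = np.log1p(-q) if q < 1.0 else -np.inf
    u = universe_size
    js = np.arange(k_observed, u + 1)
    log_terms = (
        gammaln(u + 1)
        - gammaln(js + 1)
        - gammaln(u - js + 1)
        + js * log_q
        + (u - js) * log1m_q
    )
    return float(np.exp(logsumexp(log_terms)))


@dataclass
class StabilityReport:
    """Intersection of gene sets from repeated seeded selection runs."""

    gene_sets: list[list[str]]
    set_sizes: list[int]
    intersection: list[str]
    intersection_p: float
    universe_size: int


def stability_report(gene_sets: Iterable[Iterable[str]], universe_size: int) -> StabilityReport:
    sets = [list(s) for s in gene_sets]
    common: set[str] = set(sets[0])
    for s in sets[1:]:
        common &= set(s)
    sizes = [len(s) for s in sets]
    return StabilityReport(
        gene_sets=sets,
        set_sizes=sizes,
        intersection=sorted(common),
        intersection_p=intersection_significance(sizes, universe_size, len(common)),
        universe_size=universe_size,
    )
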