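"""Gene-set over-representation and score-distribution comparisons.

Over-representation is the exact upper-tail hypergeometric probability of
seeing at least the observed overlap between a query gene list and a named
set, against a fixed background universe (e.g. all brain-expressed genes).
Per-gene CNV-tolerance scores are compared between groups with the
Wilcoxon/Mann-Whitney rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GeneSet", "OverrepResult", "set_overlap", "overrep_test", "rank_sum_test"]


@dataclass(frozen=True)
class GeneSet:
    name: str
    symbols: frozenset[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def of(cls, name: str, symbols) -> "GeneSet":
        return cls(name, frozenset(symbols))


@dataclass(frozen=True)
class OverrepResult:
    k: int  # overlap
    n: int  # query size
    K: int  # set size
    N: int  # background size
    p_value: float


def set_overlap(query: set[str], target: GeneSet) -> list[str]:
    """Exact symbol intersection, alphabetically sorted."""
    return sorted(set(query) & target.symbols)


def overrep_test(k: int, n: int, K: int, N: int) -> OverrepResult:
    """Upper-tail hypergeometric P(X >= k), X ~ Hypergeom(N, K, n).

    The survival function is evaluated in log space internally by scipy,
    so deep tails stay accurate.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverrepResult(k=k, n=n, K=K, N=N, p_value=min(p, 1.0))


def rank_sum_test(scores_a, scores_b) -> float:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum p-value.

    Exact when both groups have <= 20 observations and no ties; otherwise the
    normal approximation with mid-rank tie correction. Degenerate input (all
    values identical across both groups) returns 1 by convention.
    """
    a = np.asarray(list(scores_a), dtype=float)
    b = np.asarray(list(scores_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both score lists must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=False)
    return float(min(res.pvalue, 1.0))
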