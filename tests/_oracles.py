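"""Independent brute-force oracles used by the test suite.

Each oracle re-derives its result from first principles (path enumeration,
truth tables, exhaustive rank splits, direct mass summation) without calling
the implementation under test.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy.stats import norm

STATES = (0, 1, 2)  # DIP, DEL, DUP


def oracle_transition(distance_bp: float, p: float, attrition_bp: float) -> np.ndarray:
    """Distance-dependent transition matrix, written out longhand."""
    pi = [1.0 - 2.0 * p, p, p]
    f = math.exp(-distance_bp / attrition_bp) if math.isfinite(distance_bp) else 0.0
    t = np.array([pi, pi, pi], dtype=float)
    t[1] = [(1 - f) * pi[0], f + (1 - f) * pi[1], (1 - f) * pi[2]]
    t[2] = [(1 - f) * pi[0], (1 - f) * pi[1], f + (1 - f) * pi[2]]
    return t


def enumerate_path_logprobs(z, distances, params) -> tuple[np.ndarray, np.ndarray]:
    """All 3^n state paths with their joint log-probabilities."""
    n = len(z)
    means = np.array([0.0, params.del_mean, params.dup_mean])
    log_e = norm.logpdf(np.asarray(z)[:, None], loc=means, scale=params.emission_sd)
    log_pi = np.log([1.0 - 2.0 * params.p_cnv, params.p_cnv, params.p_cnv])
    log_trans = [
        np.log(oracle_transition(d, params.p_cnv, params.mean_cnv_attrition_bp))
        for d in distances
    ]
    grids = np.meshgrid(*([np.arange(3)] * n), indexing="ij")
    paths = np.stack([g.ravel() for g in grids], axis=1)  # (3^n, n)
    lp = log_pi[paths[:, 0]] + log_e[np.arange(n), paths].sum(axis=1)
    for t in range(1, n):
        lp = lp + log_trans[t - 1][paths[:, t - 1], paths[:, t]]
    return paths, lp


def brute_posteriors(z, distances, params) -> np.ndarray:
    """Per-target state posteriors by path enumeration."""
    paths, lp = enumerate_path_logprobs(z, distances, params)
    w = np.exp(lp - lp.max())
    w /= w.sum()
    n = len(z)
    post = np.zeros((n, 3))
    for s in STATES:
        post[:, s] = (w[:, None] * (paths == s)).sum(axis=0)
    return post


def brute_some_probability(z, distances, params, t0: int, t1: int, state: int) -> float:
    """P(>=1 target in [t0, t1] in `state` | data) by path enumeration."""
    paths, lp = enumerate_path_logprobs(z, distances, params)
    w = np.exp(lp - lp.max())
    w /= w.sum()
    hit = (paths[:, t0 : t1 + 1] == state).any(axis=1)
    return float(w[hit].sum())


def brute_viterbi_logprob(z, distances, params) -> float:
    _, lp = enumerate_path_logprobs(z, distances, params)
    return float(lp.max())


def oracle_deleterious(
    effect: str,
    predictor_hits: int,
    panel_size: int,
    cadd,
    gerp,
    phylop,
    siphy,
) -> bool:
    """Truth-table evaluation of the composite deleteriousness rule."""
    if effect in ("splicing", "stopgain", "stoploss"):
        return True
    if effect in ("insertion", "deletion"):
        return True
    if effect == "synonymous":
        return False
    conservation = sum(
        [
            gerp is not None and gerp > 3.0,
            phylop is not None and phylop > 0.95,
            siphy is not None and siphy > 10.0,
        ]
    )
    return (
        predictor_hits >= 5
        or (cadd is not None and cadd > 4.5)
        or conservation >= 2
    )


def brute_rank_sum_p(a, b) -> float:
    """Exact two-sided rank-sum p by enumerating all C(n+m, n) rank splits."""
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n = len(a)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in a)
    splits = [sum(c) for c in combinations(range(1, len(pooled) + 1), n)]
    mean = np.mean(splits)
    lo = sum(1 for s in splits if s <= obs)
    hi = sum(1 for s in splits if s >= obs)
    if obs == mean:
        return 1.0
    return min(1.0, 2.0 * min(lo, hi) / len(splits))


def brute_hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by direct summation of the hypergeometric mass function."""
    total = 0.0
    for x in range(k, min(n, K) + 1):
        total += (math.comb(K, x) * math.comb(N - K, n - x)) / math.comb(N, n)
    return total


def brute_comphet(deleted_by_sample, variants_by_sample, edges) -> set:
    """Triple loop over (sample, deleted gene, variant): expected hit keys."""
    edge_set = {frozenset(e) for e in edges}
    hits = set()
    for sample, deleted in deleted_by_sample.items():
        for var in variants_by_sample.get(sample, []):
            for d in deleted:
                if var.gene == d:
                    hits.add((sample, var.gene, var.pos, "same_gene"))
                elif frozenset((var.gene, d)) in edge_set:
                    hits.add((sample, var.gene, var.pos, "first_order"))
    return hits
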