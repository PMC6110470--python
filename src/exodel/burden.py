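"""Case-control burden of large, rare deletions with permutation p-values.

Deletions longer than a size floor whose cohort carrier frequency (counted by
reciprocal-overlap matching) stays under an internal ceiling enter the test.
Four load statistics are compared between cases and controls — deletions per
person, fraction of samples with at least one deletion, total deleted length
per person, and mean deletion length — and significance is evaluated
empirically by permuting the case/control labels (exactly, by enumerating all
labelings, when that is cheap enough).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .calls import CnvCall, reciprocal_overlap

__all__ = [
    "BurdenConfig",
    "BurdenResult",
    "STATISTICS",
    "select_burden_set",
    "burden_statistics",
    "permutation_pvalue",
]

STATISTICS = (
    "rate_per_person",
    "proportion_with_deletion",
    "total_length",
    "average_length",
)


@dataclass(frozen=True)
class BurdenConfig:
    min_length_bp: int = 400_000  # strictly greater-than
    match_overlap_fraction: float = 0.7
    max_internal_freq: float = 0.005  # strictly less-than
    n_perm: int = 10_000
    seed: int = 0
    exhaustive_max_labelings: int = 200_000

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0.0 < self.max_internal_freq < 1.0:
            raise ValueError("max_internal_freq must lie in (0, 1)")


@dataclass(frozen=True)
class BurdenResult:
    """Observed per-group statistics and one-sided empirical p-values."""

    case_values: dict[str, float]
    control_values: dict[str, float]
    p_values: dict[str, float]
    n_perm_used: int
    exhaustive: bool


def select_burden_set(
    calls: list[CnvCall], samples: list[str], cfg: BurdenConfig = BurdenConfig()
) -> list[CnvCall]:
    """Deletions with length > min_length_bp and internal carrier frequency
    < max_internal_freq across all samples (carriers counted by matching at
    the configured reciprocal overlap)."""
    large = [c for c in calls if c.length_bp > cfg.min_length_bp]
    kept = []
    n = len(samples)
    for call in large:
        carriers = {
            o.sample
            for o in large
            if reciprocal_overlap(call.interval, o.interval) >= cfg.match_overlap_fraction
        } | {call.sample}
        if len(carriers) / n < cfg.max_internal_freq:
            kept.append(call)
    return kept


def _per_sample_loads(
    calls: list[CnvCall], samples: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(deletion count, total deleted bp) per sample, in `samples` order."""
    idx = {s: i for i, s in enumerate(samples)}
    n_calls = np.zeros(len(samples))
    total_bp = np.zeros(len(samples))
    for c in calls:
        if c.sample not in idx:
            raise ValueError(f"call sample {c.sample!r} has no phenotype")
        n_calls[idx[c.sample]] += 1
        total_bp[idx[c.sample]] += c.length_bp
    return n_calls, total_bp


def _group_stats(n_calls: np.ndarray, total_bp: np.ndarray, mask: np.ndarray) -> np.ndarray:
    n = mask.sum()
    calls = n_calls[mask].sum()
    return np.array(
        [
            calls / n,
            (n_calls[mask] > 0).mean(),
            total_bp[mask].sum() / n,
            total_bp[mask].sum() / calls if calls > 0 else 0.0,
        ]
    )


def burden_statistics(
    calls: list[CnvCall], phenotypes: pd.Series
) -> dict[str, dict[str, float]]:
    """Per-group load statistics keyed by phenotype label."""
    samples = list(phenotypes.index)
    n_calls, total_bp = _per_sample_loads(calls, samples)
    labels = phenotypes.to_numpy()
    out: dict[str, dict[str, float]] = {}
    for group in pd.unique(labels):
        mask = labels == group
        if not mask.any():
            raise ValueError(f"group {group!r} is empty")
        out[str(group)] = dict(zip(STATISTICS, _group_stats(n_calls, total_bp, mask)))
    return out


def _stat_matrix(n_calls: np.ndarray, total_bp: np.ndarray, case_masks: np.ndarray) -> np.ndarray:
    """Case-minus-control statistic vector for each labeling row of case_masks."""
    n_case = case_masks.sum(axis=1)
    n_ctrl = case_masks.shape[1] - n_case
    case_calls = case_masks @ n_calls
    ctrl_calls = n_calls.sum() - case_calls
    case_bp = case_masks @ total_bp
    ctrl_bp = total_bp.sum() - case_bp
    has = (n_calls > 0).astype(float)
    case_has = case_masks @ has
    ctrl_has = has.sum() - case_has
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = case_calls / n_case - ctrl_calls / n_ctrl
        prop = case_has / n_case - ctrl_has / n_ctrl
        total = case_bp / n_case - ctrl_bp / n_ctrl
        avg = np.where(case_calls > 0, case_bp / np.maximum(case_calls, 1), 0.0) - np.where(
            ctrl_calls > 0, ctrl_bp / np.maximum(ctrl_calls, 1), 0.0
        )
    return np.column_stack([rate, prop, total, avg])


def permutation_pvalue(
    calls: list[CnvCall],
    phenotypes: pd.Series,
    cfg: BurdenConfig = BurdenConfig(),
    case_labels: set | None = None,
) -> BurdenResult:
    """One-sided (cases > controls) empirical p per burden statistic.

    ``phenotypes`` maps sample -> label; a sample counts as a case when its
    label is in ``case_labels`` (or, for a boolean series, when it is True).

    Sampled permutations use the add-one corrected estimator
    (1 + #{perm >= obs}) / (1 + n_perm); when the number of distinct
    case/control labelings is at most ``exhaustive_max_labelings``, exact
    enumeration over all labelings replaces sampling and the p-value is the
    exact tail fraction.
    """
    if case_labels is not None:
        is_case = phenotypes.isin(case_labels).to_numpy()
    elif phenotypes.dtype == bool:
        is_case = phenotypes.to_numpy()
    else:
        raise ValueError("pass case_labels for non-boolean phenotype series")
    n = len(is_case)
    n_case = int(is_case.sum())
    if n_case == 0 or n_case == n:
        raise ValueError("need at least one case and one control")
    samples = list(phenotypes.index)
    n_calls, total_bp = _per_sample_loads(calls, samples)
    observed = _stat_matrix(n_calls, total_bp, is_case[None, :])[0]

    n_labelings = comb(n, n_case)
    if n_labelings <= cfg.exhaustive_max_labelings:
        masks = np.zeros((n_labelings, n), dtype=bool)
        for i, pick in enumerate(combinations(range(n), n_case)):
            masks[i, list(pick)] = True
        perm = _stat_matrix(n_calls, total_bp, masks)
        ge = (perm >= observed[None, :] - 1e-12).sum(axis=0)
        p = ge / n_labelings
        return BurdenResult(
            case_values=dict(zip(STATISTICS, _group_stats(n_calls, total_bp, is_case))),
            control_values=dict(zip(STATISTICS, _group_stats(n_calls, total_bp, ~is_case))),
            p_values=dict(zip(STATISTICS, p)),
            n_perm_used=n_labelings,
            exhaustive=True,
        )

    rng = np.random.default_rng(cfg.seed)
    ge = np.zeros(4)
    chunk = 2000
    done = 0
    while done < cfg.n_perm:
        m = min(chunk, cfg.n_perm - done)
        masks = np.zeros((m, n), dtype=bool)
        for i in range(m):
            masks[i, rng.choice(n, size=n_case, replace=False)] = True
        perm = _stat_matrix(n_calls, total_bp, masks)
        ge += (perm >= observed[None, :] - 1e-12).sum(axis=0)
        done += m
    p = (1.0 + ge) / (1.0 + cfg.n_perm)
    return BurdenResult(
        case_values=dict(zip(STATISTICS, _group_stats(n_calls, total_bp, is_case))),
        control_values=dict(zip(STATISTICS, _group_stats(n_calls, total_bp, ~is_case))),
        p_values=dict(zip(STATISTICS, p)),
        n_perm_used=cfg.n_perm,
        exhaustive=False,
    )
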