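"""Deletion filtering, cross-cohort matching and gene annotation.

Calls survive the quality filter when their mean segment z is strictly below
the deletion threshold and Q_SOME is at least the quality floor. Case-only
screening then removes anything matched (at a reciprocal-overlap fraction) in
controls, carried by more than the allowed number of independent cases, or
present above the frequency ceiling in a reference CNV map.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .calls import DEL, CnvCall, call_length, reciprocal_overlap

__all__ = [
    "FilterConfig",
    "ReferenceCnvMap",
    "GeneModel",
    "filter_deletions",
    "case_only_filter",
    "annotate_genes",
    "build_gene_index",
    "call_length",
    "reciprocal_overlap",
]


@dataclass(frozen=True)
class FilterConfig:
    z_max: float = -3.0  # calls must be strictly below
    q_some_min: int = 60
    max_case_carriers: int = 2
    max_ref_freq: float = 0.01
    match_overlap_fraction: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 < self.match_overlap_fraction <= 1.0:
            raise ValueError("match_overlap_fraction must lie in (0, 1]")


@dataclass
class ReferenceCnvMap:
    """Named set of (chrom, start, end, frequency) intervals from a CNV catalogue."""

    name: str
    intervals: list[tuple[str, int, int, float]]

    def __post_init__(self) -> None:
        for chrom, start, end, freq in self.intervals:
            if start >= end:
                raise ValueError(f"invalid map interval {chrom}:{start}-{end}")
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"map frequency {freq} outside [0, 1]")


@dataclass
class GeneModel:
    symbol: str
    chrom: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    brain_expressed: bool = False

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"exon [{s}, {e}) outside span of {self.symbol}")


def filter_deletions(calls: list[CnvCall], cfg: FilterConfig = FilterConfig()) -> list[CnvCall]:
    """Keep DEL calls with z_mean < z_max (strict) and q_some >= q_some_min."""
    kept = []
    for c in calls:
        if c.type != DEL:
            continue
        if c.q_some is None:
            raise ValueError("calls must be scored before filtering")
        if c.z_mean < cfg.z_max and c.q_some >= cfg.q_some_min:
            kept.append(c)
    return kept


def _matches(call: CnvCall, others: list[CnvCall], frac: float) -> list[CnvCall]:
    return [o for o in others if reciprocal_overlap(call.interval, o.interval) >= frac]


def case_only_filter(
    case_calls: list[CnvCall],
    control_calls: list[CnvCall],
    maps: list[ReferenceCnvMap],
    cfg: FilterConfig = FilterConfig(),
) -> list[CnvCall]:
    """Retain case calls absent from controls, carried by few independent
    cases, and not common in any reference CNV map.

    A call is kept iff (i) no control call matches it at >= the configured
    reciprocal overlap, (ii) the number of distinct case samples with a
    matching call (including its own carrier) is <= max_case_carriers, and
    (iii) no reference-map interval with frequency > max_ref_freq matches it.
    Output order follows a deterministic (sample, chrom, start) sort, so the
    result does not depend on input ordering.
    """
    frac = cfg.match_overlap_fraction
    kept = []
    for call in case_calls:
        if _matches(call, control_calls, frac):
            continue
        carriers = {o.sample for o in _matches(call, case_calls, frac)} | {call.sample}
        if len(carriers) > cfg.max_case_carriers:
            continue
        common = False
        for ref_map in maps:
            for chrom, start, end, freq in ref_map.intervals:
                if freq > cfg.max_ref_freq and reciprocal_overlap(
                    call.interval, (chrom, start, end)
                ) >= frac:
                    common = True
                    break
            if common:
                break
        if not common:
            kept.append(call)
    return sorted(kept, key=lambda c: (c.sample, c.chrom, c.start, c.end))


def build_gene_index(genes: list[GeneModel]) -> dict[str, IntervalTree]:
    """Per-chromosome interval tree over gene spans."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        trees[g.chrom][g.start : g.end] = g
    return dict(trees)


def annotate_genes(call: CnvCall, genes: list[GeneModel] | dict[str, IntervalTree]) -> list[str]:
    """Symbols of genes whose span shares >= 1 bp with the call, sorted."""
    index = genes if isinstance(genes, dict) else build_gene_index(genes)
    tree = index.get(call.chrom)
    if tree is None:
        return []
    hits = tree.overlap(call.start, call.end)
    return sorted({iv.data.symbol for iv in hits})
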