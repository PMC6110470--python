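"""Deletion/duplication call records and interval arithmetic.

Coordinates are carried as (start, end) pairs with length defined as
``end - start`` throughout the package; codecs convert at the file
boundary (BED is native, GFF3/VCF are shifted on read).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

DEL = "DEL"
DUP = "DUP"


@dataclass(frozen=True)
class CnvCall:
    """One called copy-number segment for one sample.

    ``z_mean`` is the mean normalized read-depth z over the segment's
    targets; ``q_some`` is the phred-scaled posterior that at least one
    target in the segment is non-diploid (integer, capped at 99, ``None``
    until scored).
    """

    sample: str
    chrom: str
    start: int
    end: int
    type: str  # DEL or DUP
    n_targets: int
    z_mean: float
    q_some: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"invalid call interval [{self.start}, {self.end})")
        if self.type not in (DEL, DUP):
            raise ValueError(f"call type must be DEL or DUP, got {self.type!r}")
        if self.n_targets < 1:
            raise ValueError("call must span at least one target")
        if self.q_some is not None and not 0 <= self.q_some <= 99:
            raise ValueError("q_some must be in [0, 99]")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def scored(self, q_some: int) -> "CnvCall":
        return replace(self, q_some=q_some)


def call_length(call: CnvCall) -> int:
    """Length in bp of a call, defined as end - start."""
    return call.end - call.start


def overlap_bp(a: tuple[str, int, int], b: tuple[str, int, int]) -> int:
    """Number of shared bases between two half-open intervals (0 across chroms)."""
    if a[0] != b[0]:
        return 0
    return max(0, min(a[2], b[2]) - max(a[1], b[1]))


def reciprocal_overlap(a: tuple[str, int, int], b: tuple[str, int, int]) -> float:
    """min(|a∩b|/|a|, |a∩b|/|b|); symmetric, 0 for different chromosomes."""
    for iv in (a, b):
        if iv[1] >= iv[2]:
            raise ValueError(f"invalid interval {iv}")
    shared = overlap_bp(a, b)
    if shared == 0:
        return 0.0
    return min(shared / (a[2] - a[1]), shared / (b[2] - b[1]))
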