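"""Variant-level QC, normalization, rarity and deleteriousness classification.

The composite classifier calls a variant deleterious when any of three
criteria fires: (1) a non-synonymous change supported by a quorum of missense
predictors, a high CADD score, or conserved position (2 of 3 conservation
predicates); (2) a splicing / stop-gain / stop-loss annotation; (3) any
insertion or deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "Genotype",
    "VariantRecord",
    "SiteFilterConfig",
    "ClassifierConfig",
    "PREDICTOR_PANEL",
    "apply_genotype_qc",
    "apply_site_filters",
    "decompose_and_normalize",
    "is_rare",
    "classify_deleterious",
]

PREDICTOR_PANEL = (
    "SIFT",
    "Polyphen2_HDIV",
    "Polyphen2_HVAR",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "MetaSVM",
    "MetaLR",
)

EFFECT_CLASSES = {
    "synonymous",
    "missense",
    "splicing",
    "stopgain",
    "stoploss",
    "insertion",
    "deletion",
    "other",
}

_LOF_EFFECTS = {"splicing", "stopgain", "stoploss"}
_INDEL_EFFECTS = {"insertion", "deletion"}
_BASES = set("ACGT")


@dataclass(frozen=True)
class Genotype:
    """Per-sample genotype; alleles is None when the call is missing."""

    alleles: Optional[tuple[int, int]]
    dp: int
    gq: int

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def has_alt(self) -> bool:
        return self.alleles is not None and any(a > 0 for a in self.alleles)


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    gene: str = ""
    effect: str = "other"
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    site: dict[str, float] = field(default_factory=dict)  # QD, FS, MQ, ... VQSLOD
    predictors: dict[str, str] = field(default_factory=dict)  # name -> deleterious/tolerated/missing
    cadd: Optional[float] = None
    gerp: Optional[float] = None
    phylop: Optional[float] = None
    siphy: Optional[float] = None
    afs: dict[str, float] = field(default_factory=dict)  # database -> allele frequency

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based)")
        for allele in (self.ref, *self.alts):
            if not allele or set(allele) - _BASES:
                raise ValueError(f"allele {allele!r} must be a non-empty ACGT string")
        if self.effect not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect!r}")
        for db, af in self.afs.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency {af} for {db} outside [0, 1]")

    @property
    def missingness(self) -> float:
        if not self.genotypes:
            return 0.0
        return sum(g.is_missing for g in self.genotypes.values()) / len(self.genotypes)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or any(len(a) != 1 for a in self.alts)


def apply_genotype_qc(record: VariantRecord, dp_min: int = 10, gq_min: int = 20) -> VariantRecord:
    """Set genotypes with DP < dp_min or GQ < gq_min to missing.

    Allele fields are untouched; only genotype calls (and hence site
    missingness) change.
    """
    new = {
        s: (replace(g, alleles=None) if (g.dp < dp_min or g.gq < gq_min) else g)
        for s, g in record.genotypes.items()
    }
    out = replace(record, genotypes=new)
    out.site = dict(record.site)
    out.site["missingness"] = out.missingness
    return out


# predicate name -> (annotation key, test on the annotation value)
_SNV_PREDICATES = {
    "QD": ("QD", lambda v: v < 2.0),
    "FS": ("FS", lambda v: v > 60.0),
    "MQ": ("MQ", lambda v: v < 40.0),
    "MQRankSum": ("MQRankSum", lambda v: v < -12.5),
    "ReadPosRankSum": ("ReadPosRankSum", lambda v: v < -8.0),
    "DP": ("DP", lambda v: v < 10.0),
    "GQ_MEAN": ("GQ_MEAN", lambda v: v < 20.0),
    "missingness": ("missingness", lambda v: v > 0.05),
    "ABHet": ("ABHet", lambda v: v > 0.75 or v < 0.25),
    "HWE": ("HWE_PHRED", lambda v: v > 20.0),  # phred-scaled HWE p, i.e. p < 0.01
}

_INDEL_PREDICATES = {
    "QD": ("QD", lambda v: v < 2.0),
    "FS": ("FS", lambda v: v > 200.0),
    "ReadPosRankSum": ("ReadPosRankSum", lambda v: v < -20.0),
    "DP": ("DP", lambda v: v < 10.0),
    "GQ_MEAN": ("GQ_MEAN", lambda v: v < 20.0),
    "missingness": ("missingness", lambda v: v > 0.05),
    "HWE": ("HWE_PHRED", lambda v: v > 20.0),
}


@dataclass(frozen=True)
class SiteFilterConfig:
    """Site-level hard filters; mode selects the SNV or INDEL threshold set.

    ``vqslod_fail_below`` is the VQSLOD cut-off under which a site fails
    (the recalibration directionality for indels is ambiguous in common
    usage, so it is an explicit knob rather than a constant).
    ``strict_missing`` makes an absent annotation a failure instead of a
    pass-by-absence.
    """

    mode: str = "SNV"
    vqslod_fail_below: float = 0.0
    strict_missing: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("SNV", "INDEL"):
            raise ValueError("mode must be SNV or INDEL")

    @property
    def predicates(self):
        return _SNV_PREDICATES if self.mode == "SNV" else _INDEL_PREDICATES


def apply_site_filters(record: VariantRecord, cfg: SiteFilterConfig) -> tuple[bool, list[str]]:
    """Return (passed, tripped-predicate names). Missing annotations pass
    unless strict_missing is set."""
    site = dict(record.site)
    site.setdefault("missingness", record.missingness)
    reasons = []
    for name, (key, bad) in cfg.predicates.items():
        if key not in site:
            if cfg.strict_missing:
                reasons.append(name)
            continue
        if bad(site[key]):
            reasons.append(name)
    if "VQSLOD" in site:
        if site["VQSLOD"] < cfg.vqslod_fail_below:
            reasons.append("VQSLOD")
    elif cfg.strict_missing:
        reasons.append("VQSLOD")
    return (not reasons, reasons)


@dataclass(frozen=True)
class ReferenceContext:
    """Reference bases around a variant; ``offset`` is the 1-based position
    of the first base of ``seq``."""

    chrom: str
    offset: int
    seq: str

    def base(self, pos: int) -> str:
        i = pos - self.offset
        if i < 0 or i >= len(self.seq):
            raise ValueError(f"position {pos} outside reference context")
        return self.seq[i]

    def slice(self, pos: int, length: int) -> str:
        return "".join(self.base(pos + k) for k in range(length))


def _normalize_alleles(pos: int, ref: str, alt: str, ctx: ReferenceContext) -> tuple[int, str, str]:
    # right-trim shared suffix, extending left from the reference when an
    # allele would empty; then left-trim shared prefix (vt-style)
    while True:
        if ref[-1] == alt[-1]:
            if len(ref) == 1 or len(alt) == 1:
                pos -= 1
                pad = ctx.base(pos)
                ref, alt = pad + ref, pad + alt
            ref, alt = ref[:-1], alt[:-1]
        else:
            break
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def decompose_and_normalize(
    record: VariantRecord, reference_context: ReferenceContext
) -> list[VariantRecord]:
    """Split multi-allelic records and left-align/trim each alt allele.

    Idempotent: running the result through again changes nothing. Raises if
    the record's ref allele disagrees with the reference context.
    """
    if reference_context.slice(record.pos, len(record.ref)) != record.ref:
        raise ValueError(
            f"ref allele {record.ref!r} at {record.chrom}:{record.pos} "
            "does not match the reference context"
        )
    out = []
    for alt in record.alts:
        pos, ref, norm_alt = _normalize_alleles(record.pos, record.ref, alt, reference_context)
        out.append(replace(record, pos=pos, ref=ref, alts=(norm_alt,)))
    return out


@dataclass(frozen=True)
class ClassifierConfig:
    min_predictor_hits: int = 5
    predictor_panel: tuple[str, ...] = PREDICTOR_PANEL
    cadd_min: float = 4.5
    gerp_min: float = 3.0
    phylop_min: float = 0.95
    siphy_min: float = 10.0
    min_conservation_hits: int = 2
    maf_max: float = 0.005

    def __post_init__(self) -> None:
        if self.min_predictor_hits > len(self.predictor_panel):
            raise ValueError("min_predictor_hits exceeds panel size")


def is_rare(record: VariantRecord, cfg: ClassifierConfig = ClassifierConfig()) -> bool:
    """True iff MAF < maf_max (strict) in every database carrying the variant;
    absence from a database counts as frequency 0."""
    return all(af < cfg.maf_max for af in record.afs.values())


def classify_deleterious(
    record: VariantRecord, cfg: ClassifierConfig = ClassifierConfig()
) -> tuple[bool, list[str]]:
    """Composite deleteriousness verdict with the criteria that fired.

    Criteria: ``lof`` — splicing/stop-gain/stop-loss; ``indel`` — any
    insertion or deletion; ``scores`` — non-synonymous with a predictor
    quorum, CADD above threshold, or 2-of-3 conservation. Missing predictor
    calls never count toward the quorum.
    """
    fired = []
    if record.effect in _LOF_EFFECTS:
        fired.append("lof")
    if record.effect in _INDEL_EFFECTS:
        fired.append("indel")
    if record.effect != "synonymous":
        hits = sum(
            record.predictors.get(p) == "deleterious" for p in cfg.predictor_panel
        )
        cons = sum(
            (
                record.gerp is not None and record.gerp > cfg.gerp_min,
                record.phylop is not None and record.phylop > cfg.phylop_min,
                record.siphy is not None and record.siphy > cfg.siphy_min,
            )
        )
        if (
            hits >= cfg.min_predictor_hits
            or (record.cadd is not None and record.cadd > cfg.cadd_min)
            or cons >= cfg.min_conservation_hits
        ):
            fired.append("scores")
    return (bool(fired), fired)
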