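"""Seeded synthetic cohorts with the structure the pipeline assumes.

The generator emulates an exome-sequenced two-phenotype case cohort plus
population controls: per-target mean read depth with overdispersed
(negative-binomial) counts, per-sample size factors, multiplicative low-rank
batch structure for the PCA stage to remove, and embedded heterozygous
deletions at copy ratio 0.5; annotated variant tables carrying the missense
predictor panel, CADD, conservation scores and population allele
frequencies; an interaction network; reference CNV frequency maps; and gene
sets. One global seed drives independent child streams per generator, so
adding a generator never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .caller import DepthMatrix
from .calls import overlap_bp
from .network import InteractionNetwork
from .postprocess import GeneModel, ReferenceCnvMap
from .variants import PREDICTOR_PANEL, Genotype, VariantRecord

__all__ = [
    "SimConfig",
    "DeletionSpec",
    "VariantSpec",
    "NetworkSpec",
    "RefMapSpec",
    "GeneSetSpec",
    "TruthTable",
    "simulate_depth_cohort",
    "simulate_gene_models",
    "simulate_variant_table",
    "simulate_network",
    "simulate_reference_maps",
    "simulate_gene_sets",
]

PHENO_CASE_A = "GGE"  # generalized-epilepsy-like case group
PHENO_CASE_B = "RE"  # Rolandic-epilepsy-like case group
PHENO_CONTROL = "CTRL"

_STREAMS = {
    "layout": 0,
    "depth": 1,
    "variants": 2,
    "network": 3,
    "maps": 4,
    "genesets": 5,
    "genes": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class DeletionSpec:
    """One deletion locus to embed: which phenotypes carry it, at what
    fraction of the eligible samples, over how many consecutive targets."""

    phenotypes: tuple[str, ...] = (PHENO_CASE_A,)
    carrier_fraction: float = 0.01
    n_targets: int = 12
    copy_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must lie in [0, 1]")
        if not 0.0 < self.copy_ratio <= 1.0:
            raise ValueError("copy_ratio must lie in (0, 1]")
        if self.n_targets < 1:
            raise ValueError("deletion must span >= 1 target")


@dataclass(frozen=True)
class VariantSpec:
    per_gene_rate: float = 1.0  # Poisson mean variants per gene
    effect_probs: tuple[tuple[str, float], ...] = (
        ("synonymous", 0.30),
        ("missense", 0.45),
        ("splicing", 0.05),
        ("stopgain", 0.05),
        ("stoploss", 0.01),
        ("insertion", 0.07),
        ("deletion", 0.07),
    )
    frac_predictor_deleterious: float = 0.25  # missense with a >=5/9 predictor quorum
    frac_high_cadd: float = 0.25
    frac_conserved: float = 0.25
    rare_fraction: float = 0.9  # MAF < 0.005 in every database
    mean_carriers: float = 2.0
    low_quality_fraction: float = 0.05  # genotypes failing DP/GQ QC
    databases: tuple[str, ...] = ("KG1000", "DBSNP", "EXAC", "EVS")


@dataclass(frozen=True)
class NetworkSpec:
    n_genes: int = 2000
    mean_degree: float = 10.0
    brain_expressed_fraction: float = 0.78

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("network needs >= 2 genes")
        if self.mean_degree >= self.n_genes:
            raise ValueError("mean degree must be < number of genes")


@dataclass(frozen=True)
class RefMapSpec:
    names: tuple[str, ...] = ("cnvmap", "dgv_gold", "kg_sv")
    n_background: int = 100  # random intervals per map
    n_common_truth_loci: int = 0  # truth loci to plant at >1% frequency
    common_freq: float = 0.05


@dataclass(frozen=True)
class GeneSetSpec:
    n_sets: int = 3
    set_size: int = 80
    enrichment_weight: float = 10.0  # sampling weight of favoured genes


@dataclass(frozen=True)
class SimConfig:
    n_cases_a: int = 196
    n_cases_b: int = 194
    n_controls: int = 572
    n_targets: int = 5000
    n_chroms: int = 5
    target_length_mean: float = 150.0
    target_length_sd: float = 50.0
    target_gap_mean: float = 1000.0
    depth_mean: float = 100.0
    depth_dispersion: float = 200.0  # NB size; var = mu + mu^2/size
    target_log_sd: float = 0.3  # capture-efficiency spread across targets
    sample_log_sd: float = 0.2  # library-size spread across samples
    batch_rank: int = 2
    batch_sd: float = 0.1
    targets_per_gene: int = 3
    deletion_spec: tuple[DeletionSpec, ...] = ()
    variant_spec: VariantSpec = field(default_factory=VariantSpec)
    network_spec: NetworkSpec = field(default_factory=NetworkSpec)
    refmap_spec: RefMapSpec = field(default_factory=RefMapSpec)
    geneset_spec: GeneSetSpec = field(default_factory=GeneSetSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases_a", "n_cases_b", "n_controls"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_targets", "n_chroms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_samples < 2:
            raise ValueError("cohort needs >= 2 samples")

    @property
    def n_samples(self) -> int:
        return self.n_cases_a + self.n_cases_b + self.n_controls

    def sample_ids(self) -> list[str]:
        return (
            [f"{PHENO_CASE_A}{i:04d}" for i in range(1, self.n_cases_a + 1)]
            + [f"{PHENO_CASE_B}{i:04d}" for i in range(1, self.n_cases_b + 1)]
            + [f"{PHENO_CONTROL}{i:04d}" for i in range(1, self.n_controls + 1)]
        )

    def phenotypes(self) -> pd.Series:
        labels = (
            [PHENO_CASE_A] * self.n_cases_a
            + [PHENO_CASE_B] * self.n_cases_b
            + [PHENO_CONTROL] * self.n_controls
        )
        return pd.Series(labels, index=self.sample_ids(), name="phenotype")


@dataclass
class TruthTable:
    """Ground truth of everything the generator embedded."""

    deletions: pd.DataFrame  # sample, chrom, start, end, copy_ratio, locus, t0, t1
    variants: pd.DataFrame  # sample, gene, criterion
    phenotypes: pd.Series  # sample -> phenotype label


def _target_layout(config: SimConfig) -> pd.DataFrame:
    """1-based target coordinates on a few synthetic chromosomes."""
    rng = _rng(config.seed, "layout")
    per_chrom = np.full(config.n_chroms, config.n_targets // config.n_chroms)
    per_chrom[: config.n_targets % config.n_chroms] += 1
    rows = []
    for c, n_t in enumerate(per_chrom, start=1):
        pos = 1
        for _ in range(n_t):
            gap = int(rng.exponential(config.target_gap_mean)) + 1
            length = max(50, int(rng.normal(config.target_length_mean, config.target_length_sd)))
            start = pos + gap
            rows.append((f"chr{c}", start, start + length))
            pos = start + length
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _place_deletions(
    config: SimConfig, targets: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Choose non-overlapping target runs and carriers for each deletion spec."""
    chrom = targets["chrom"].to_numpy()
    phenos = config.phenotypes()
    taken = np.zeros(len(targets), dtype=bool)
    records = []
    for locus, spec in enumerate(config.deletion_spec):
        runs = [
            t0
            for t0 in range(len(targets) - spec.n_targets + 1)
            if chrom[t0] == chrom[t0 + spec.n_targets - 1]
            and not taken[max(0, t0 - 2) : t0 + spec.n_targets + 2].any()
        ]
        if not runs:
            raise ValueError(
                f"deletion spec {locus} ({spec.n_targets} targets) exceeds the "
                "available target space"
            )
        t0 = int(rng.choice(runs))
        t1 = t0 + spec.n_targets - 1
        taken[t0 : t1 + 1] = True
        eligible = phenos.index[phenos.isin(spec.phenotypes)].to_numpy()
        n_carriers = int(round(spec.carrier_fraction * len(eligible)))
        carriers = rng.choice(eligible, size=n_carriers, replace=False)
        for s in carriers:
            records.append(
                (
                    s,
                    str(chrom[t0]),
                    int(targets["start"].iloc[t0]),
                    int(targets["end"].iloc[t1]),
                    spec.copy_ratio,
                    locus,
                    t0,
                    t1,
                )
            )
    return pd.DataFrame(
        records,
        columns=["sample", "chrom", "start", "end", "copy_ratio", "locus", "t0", "t1"],
    )


def simulate_depth_cohort(config: SimConfig) -> tuple[DepthMatrix, TruthTable]:
    """Simulate the sample x target mean-depth matrix plus its ground truth.

    Expected depth factorizes as
    depth_mean * target_effect * sample_size_factor * batch * copy_ratio,
    and counts are negative-binomial around it.
    """
    targets = _target_layout(config)
    rng = _rng(config.seed, "depth")
    n, t_len = config.n_samples, len(targets)
    target_effect = np.exp(rng.normal(0.0, config.target_log_sd, size=t_len))
    sample_effect = np.exp(rng.normal(0.0, config.sample_log_sd, size=n))
    log_batch = np.zeros((n, t_len))
    for _ in range(config.batch_rank):
        loading = rng.normal(0.0, config.batch_sd, size=n)
        direction = rng.normal(0.0, 1.0, size=t_len)
        log_batch += np.outer(loading, direction)
    mu = config.depth_mean * sample_effect[:, None] * target_effect[None, :] * np.exp(log_batch)
    deletions = _place_deletions(config, targets, rng)
    sample_ids = config.sample_ids()
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    copy = np.ones((n, t_len))
    for row in deletions.itertuples():
        copy[sample_index[row.sample], row.t0 : row.t1 + 1] = row.copy_ratio
    mu = mu * copy
    size = config.depth_dispersion
    depth = rng.negative_binomial(size, size / (size + mu)).astype(float)
    matrix = DepthMatrix(sample_ids, targets, depth)
    truth = TruthTable(
        deletions=deletions,
        variants=pd.DataFrame(columns=["sample", "gene", "criterion"]),
        phenotypes=config.phenotypes(),
    )
    return matrix, truth


def simulate_gene_models(config: SimConfig) -> list[GeneModel]:
    """Tile consecutive targets into synthetic genes (targets as exons)."""
    targets = _target_layout(config)
    rng = _rng(config.seed, "genes")
    genes: list[GeneModel] = []
    k = config.targets_per_gene
    gid = 0
    for chrom, grp in targets.groupby("chrom", sort=False):
        rows = grp.reset_index(drop=True)
        for i in range(0, len(rows) - k + 1, k):
            block = rows.iloc[i : i + k]
            gid += 1
            genes.append(
                GeneModel(
                    symbol=f"GENE{gid:05d}",
                    chrom=str(chrom),
                    start=int(block["start"].iloc[0]),
                    end=int(block["end"].iloc[-1]),
                    exons=[(int(r.start), int(r.end)) for r in block.itertuples()],
                    brain_expressed=bool(rng.random() < 0.78),
                )
            )
    return genes


def _draw_afs(rng: np.random.Generator, rare: bool, databases: tuple[str, ...]) -> dict[str, float]:
    if rare:
        base = 10.0 ** rng.uniform(-5.0, np.log10(0.004))
    else:
        base = rng.uniform(0.006, 0.2)
    return {
        db: float(np.clip(base * rng.uniform(0.8, 1.2), 0.0, 1.0)) for db in databases
    }


def simulate_variant_table(config: SimConfig, genes: list[GeneModel]) -> list[VariantRecord]:
    """Annotated small-variant records over the given gene models."""
    if not genes:
        raise ValueError("gene models must be non-empty")
    rng = _rng(config.seed, "variants")
    spec = config.variant_spec
    effects = [e for e, _ in spec.effect_probs]
    probs = np.array([p for _, p in spec.effect_probs])
    probs = probs / probs.sum()
    sample_ids = np.array(config.sample_ids())
    bases = np.array(list("ACGT"))
    records: list[VariantRecord] = []
    for gene in genes:
        for _ in range(rng.poisson(spec.per_gene_rate)):
            effect = str(rng.choice(effects, p=probs))
            pos = int(rng.integers(gene.start, gene.end))
            ref = str(rng.choice(bases))
            if effect == "insertion":
                alt = ref + "".join(rng.choice(bases, size=int(rng.integers(1, 4))))
            elif effect == "deletion":
                ref = ref + "".join(rng.choice(bases, size=int(rng.integers(1, 4))))
                alt = ref[0]
            else:
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            predictors = {p: "missing" for p in PREDICTOR_PANEL}
            if effect == "missense":
                hi = rng.random() < spec.frac_predictor_deleterious
                n_del = int(rng.integers(5, 10)) if hi else int(rng.integers(0, 5))
                order = rng.permutation(len(PREDICTOR_PANEL))
                for j, pi in enumerate(order):
                    predictors[PREDICTOR_PANEL[pi]] = (
                        "deleterious" if j < n_del else "tolerated"
                    )
            if rng.random() < spec.frac_high_cadd:
                cadd = float(rng.uniform(4.6, 40.0))
            else:
                cadd = float(rng.uniform(0.0, 4.4))
            if rng.random() < spec.frac_conserved:
                gerp, phylop, siphy = (
                    float(rng.uniform(3.1, 6.0)),
                    float(rng.uniform(0.96, 2.5)),
                    float(rng.uniform(10.5, 20.0)),
                )
            else:
                gerp, phylop, siphy = (
                    float(rng.uniform(-2.0, 2.9)),
                    float(rng.uniform(-1.0, 0.9)),
                    float(rng.uniform(0.0, 9.5)),
                )
            rare = rng.random() < spec.rare_fraction
            n_carriers = min(1 + rng.poisson(max(spec.mean_carriers - 1.0, 0.0)), len(sample_ids))
            carriers = rng.choice(sample_ids, size=n_carriers, replace=False)
            genotypes = {}
            for s in carriers:
                if rng.random() < spec.low_quality_fraction:
                    dp, gq = int(rng.integers(0, 10)), int(rng.integers(0, 20))
                else:
                    dp, gq = int(rng.integers(15, 80)), int(rng.integers(30, 100))
                genotypes[str(s)] = Genotype(alleles=(0, 1), dp=dp, gq=gq)
            site = {
                "QD": float(rng.uniform(5.0, 30.0)),
                "FS": float(rng.uniform(0.0, 20.0)),
                "MQ": float(rng.uniform(50.0, 60.0)),
                "MQRankSum": float(rng.normal(0.0, 1.0)),
                "ReadPosRankSum": float(rng.normal(0.0, 1.0)),
                "DP": float(rng.uniform(20.0, 200.0)),
                "GQ_MEAN": float(rng.uniform(40.0, 95.0)),
                "VQSLOD": float(rng.uniform(0.5, 10.0)),
                "ABHet": float(rng.uniform(0.35, 0.65)),
                "HWE_PHRED": float(rng.uniform(0.0, 10.0)),
            }
            records.append(
                VariantRecord(
                    chrom=gene.chrom,
                    pos=pos,
                    ref=ref,
                    alts=(alt,),
                    gene=gene.symbol,
                    effect=effect,
                    genotypes=genotypes,
                    site=site,
                    predictors=predictors,
                    cadd=cadd,
                    gerp=gerp,
                    phylop=phylop,
                    siphy=siphy,
                    afs=_draw_afs(rng, rare, spec.databases),
                )
            )
    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alts))
    return records


def simulate_network(config: SimConfig, genes: list[str]) -> InteractionNetwork:
    """Erdos-Renyi interaction network over the given gene symbols."""
    spec = config.network_spec
    if len(genes) < 2:
        raise ValueError("network needs >= 2 gene symbols")
    if spec.mean_degree >= len(genes):
        raise ValueError("mean degree must be < number of genes")
    rng = _rng(config.seed, "network")
    p = spec.mean_degree / (len(genes) - 1)
    g = nx.fast_gnp_random_graph(len(genes), p, seed=int(rng.integers(2**31)))
    mapping = dict(enumerate(genes))
    g = nx.relabel_nodes(g, mapping)
    g.add_nodes_from(genes)
    brain = {s for s in genes if rng.random() < spec.brain_expressed_fraction}
    for node in g.nodes:
        g.nodes[node]["brain_expressed"] = node in brain
    return InteractionNetwork(g)


def simulate_reference_maps(config: SimConfig, truth: TruthTable) -> list[ReferenceCnvMap]:
    """Reference CNV frequency maps; optionally plant truth loci as common.

    Background intervals that happen to overlap a truth deletion are capped
    at the rare-frequency ceiling, so only deliberately planted loci are
    removable by the frequency filter.
    """
    spec = config.refmap_spec
    rng = _rng(config.seed, "maps")
    targets = _target_layout(config)
    span_by_chrom = {
        str(c): int(grp["end"].max()) for c, grp in targets.groupby("chrom", sort=False)
    }
    loci = (
        truth.deletions.drop_duplicates("locus").sort_values("locus")
        if len(truth.deletions)
        else truth.deletions
    )
    n_common = min(spec.n_common_truth_loci, len(loci))
    common = loci.iloc[:n_common] if n_common else loci.iloc[:0]
    truth_ivs = [
        (str(r.chrom), int(r.start), int(r.end)) for r in truth.deletions.itertuples()
    ]
    maps = []
    for name in spec.names:
        intervals: list[tuple[str, int, int, float]] = []
        for _ in range(spec.n_background):
            chrom = str(rng.choice(list(span_by_chrom)))
            length = int(rng.integers(500, 200_000))
            start = int(rng.integers(1, max(span_by_chrom[chrom] - length, 2)))
            freq = float(10.0 ** rng.uniform(-4.0, -0.5))
            iv = (chrom, start, start + length)
            if any(overlap_bp(iv, tiv) > 0 for tiv in truth_ivs):
                freq = min(freq, 0.009)
            intervals.append((*iv, freq))
        for r in common.itertuples():
            jitter = int(rng.integers(0, max((r.end - r.start) // 10, 1)))
            intervals.append((str(r.chrom), int(r.start) + jitter, int(r.end) + jitter, spec.common_freq))
        maps.append(ReferenceCnvMap(name=name, intervals=intervals))
    return maps


def simulate_gene_sets(
    config: SimConfig, universe: list[str], favoured: set[str] = frozenset()
) -> list:
    """Named gene sets drawn from the universe.

    The first set oversamples ``favoured`` genes by the configured
    enrichment weight (a truly enriched set); the remaining sets are drawn
    uniformly (null sets).
    """
    from .enrich import GeneSet

    spec = config.geneset_spec
    rng = _rng(config.seed, "genesets")
    weights = np.array(
        [spec.enrichment_weight if g in favoured else 1.0 for g in universe], dtype=float
    )
    weights /= weights.sum()
    sets = []
    for i in range(spec.n_sets):
        p = weights if i == 0 else None
        members = rng.choice(
            universe, size=min(spec.set_size, len(universe)), replace=False, p=p
        )
        sets.append(GeneSet.of(f"SET{i + 1:02d}", members))
    return sets
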