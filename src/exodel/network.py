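"""Protein-interaction network handling and the compound-heterozygote screen.

A sample is a compound-het candidate when one allele of a gene is removed by
a deletion and the same sample carries a rare deleterious small variant in
the same gene (``same_gene``) or in a direct interaction partner
(``first_order``). Phasing is unavailable, so "the other allele" is
operationalized as any passing deleterious variant in the deletion carrier.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

__all__ = [
    "InteractionNetwork",
    "CompHetHit",
    "build_brain_network",
    "find_comphet_hits",
]


@dataclass
class InteractionNetwork:
    """Undirected simple gene graph with a brain_expressed node flag."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed")

    @classmethod
    def from_edges(
        cls, edges: list[tuple[str, str]], brain_expressed: set[str] | None = None
    ) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_edges_from((u, v) for u, v in edges if u != v)
        brain = brain_expressed or set()
        for node in g.nodes:
            g.nodes[node]["brain_expressed"] = node in brain
        return cls(g)

    @property
    def n_genes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_interactions(self) -> int:
        return self.graph.number_of_edges()

    def brain_genes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("brain_expressed")}

    def neighbors(self, gene: str) -> set[str]:
        if gene not in self.graph:
            return set()
        return set(self.graph.neighbors(gene))


@dataclass(frozen=True)
class CompHetHit:
    sample: str
    deleted_genes: tuple[str, ...]
    variant_gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    annotation: str
    relation: str  # same_gene | first_order

    def __post_init__(self) -> None:
        if self.relation not in ("same_gene", "first_order"):
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.relation == "same_gene" and self.variant_gene not in self.deleted_genes:
            raise ValueError("same_gene hit requires the variant gene among deleted genes")


def build_brain_network(
    net: InteractionNetwork, valid_symbols: set[str], brain_genes: set[str]
) -> InteractionNetwork:
    """Restrict to nomenclature-valid, brain-expressed genes.

    Edges survive only when both endpoints survive; no transitive closure is
    taken, so removing an intermediate gene disconnects its neighbours.
    """
    keep = (set(net.graph.nodes) & valid_symbols) & brain_genes
    sub = net.graph.subgraph(keep).copy()
    for node in sub.nodes:
        sub.nodes[node]["brain_expressed"] = True
    return InteractionNetwork(sub)


@dataclass(frozen=True)
class DeleteriousVariant:
    """Minimal view of a passing rare deleterious variant for the screen."""

    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    annotation: str


def find_comphet_hits(
    deleted_genes_by_sample: dict[str, set[str]],
    deleterious_variants_by_sample: dict[str, list[DeleteriousVariant]],
    net: InteractionNetwork,
) -> list[CompHetHit]:
    """Screen each sample for deletion + deleterious-variant concurrence.

    Emits a ``same_gene`` hit when a deleted gene also carries a deleterious
    variant in that sample, and a ``first_order`` hit when the variant gene
    is a direct network neighbour of a deleted gene. Genes absent from the
    network are skipped for first_order but stay eligible for same_gene.
    Output is ordered by (sample, variant gene, position, relation).
    """
    hits: list[CompHetHit] = []
    for sample in sorted(deleted_genes_by_sample):
        deleted = deleted_genes_by_sample[sample]
        if not deleted:
            continue
        for var in deleterious_variants_by_sample.get(sample, []):
            if var.gene in deleted:
                hits.append(
                    CompHetHit(
                        sample=sample,
                        deleted_genes=(var.gene,),
                        variant_gene=var.gene,
                        chrom=var.chrom,
                        pos=var.pos,
                        ref=var.ref,
                        alt=var.alt,
                        annotation=var.annotation,
                        relation="same_gene",
                    )
                )
            partners = net.neighbors(var.gene) & deleted
            partners -= {var.gene}
            if partners:
                hits.append(
                    CompHetHit(
                        sample=sample,
                        deleted_genes=tuple(sorted(partners)),
                        variant_gene=var.gene,
                        chrom=var.chrom,
                        pos=var.pos,
                        ref=var.ref,
                        alt=var.alt,
                        annotation=var.annotation,
                        relation="first_order",
                    )
                )
    hits.sort(key=lambda h: (h.sample, h.variant_gene, h.pos, h.relation))
    return hits
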