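#!/usr/bin/env python
"""Small-variant QC and deleteriousness classification, then the
compound-heterozygote screen: deletions paired with rare deleterious
variants in the same gene or a first-order partner on the brain-specific
interaction network."""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS, SCRATCH  # noqa: E402

import pandas as pd  # noqa: E402

from exodel import io  # noqa: E402
from exodel.network import (  # noqa: E402
    DeleteriousVariant,
    build_brain_network,
    find_comphet_hits,
)
from exodel.variants import (  # noqa: E402
    SiteFilterConfig,
    apply_genotype_qc,
    apply_site_filters,
    classify_deleterious,
    is_rare,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()

    records, _ = io.read_vcf(SCRATCH / "cohort" / "variants.vcf")
    genes = io.read_gene_models(RESULTS / "cohort" / "genes.bed")
    net = io.read_network_tsv(
        RESULTS / "cohort" / "ppin_edges.tsv", RESULTS / "cohort" / "ppin_nodes.tsv"
    )
    deleted_genes = pd.read_csv(RESULTS / "03_deleted_genes.tsv", sep="\t")

    snv_cfg, indel_cfg = SiteFilterConfig("SNV"), SiteFilterConfig("INDEL")
    n_site_fail = n_not_rare = n_benign = 0
    deleterious = []
    for rec in records:
        rec = apply_genotype_qc(rec)
        ok, _ = apply_site_filters(rec, indel_cfg if rec.is_indel else snv_cfg)
        if not ok:
            n_site_fail += 1
            continue
        if not is_rare(rec):
            n_not_rare += 1
            continue
        flag, _ = classify_deleterious(rec)
        if not flag:
            n_benign += 1
            continue
        deleterious.append(rec)

    by_sample: dict[str, list[DeleteriousVariant]] = {}
    for rec in deleterious:
        view = DeleteriousVariant(gene=rec.gene, chrom=rec.chrom, pos=rec.pos,
                                  ref=rec.ref, alt=rec.alts[0], annotation=rec.effect)
        for sample, g in rec.genotypes.items():
            if g.has_alt:
                by_sample.setdefault(sample, []).append(view)

    deleted_by_sample = {
        s: set(grp["gene"]) for s, grp in deleted_genes.groupby("sample")
    }
    brain = {g.symbol for g in genes if g.brain_expressed}
    brain_net = build_brain_network(net, {g.symbol for g in genes}, brain)
    hits = find_comphet_hits(deleted_by_sample, by_sample, brain_net)

    table = pd.DataFrame(
        [
            (h.variant_gene, ";".join(h.deleted_genes), h.sample, h.relation,
             h.chrom, h.pos, h.ref, h.alt, h.annotation)
            for h in hits
        ],
        columns=["variant_gene", "deleted_genes", "sample", "relation",
                 "chrom", "pos", "ref", "alt", "annotation"],
    )
    table.to_csv(RESULTS / "05_comphet_hits.tsv", sep="\t", index=False)

    print(f"variants: {len(records)} -> site-filter fails {n_site_fail}, "
          f"common {n_not_rare}, benign {n_benign}, "
          f"rare deleterious {len(deleterious)}")
    print(f"brain network: {net.n_genes} genes / {net.n_interactions} edges -> "
          f"{brain_net.n_genes} / {brain_net.n_interactions} after filtering")
    n_same = sum(h.relation == "same_gene" for h in hits)
    print(f"compound-het hits: {len(hits)} ({n_same} same-gene, "
          f"{len(hits) - n_same} first-order) -> {RESULTS / '05_comphet_hits.tsv'}")


if __name__ == "__main__":
    main()
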