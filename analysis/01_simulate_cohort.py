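#!/usr/bin/env python
"""Generate the study cohort: depth matrix, truth tables, gene models,
variant calls, interaction network and reference CNV maps.

Small tables go to results/, the bulky depth matrix and VCF to scratch/.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS, SCRATCH, study_config  # noqa: E402

from exodel import io  # noqa: E402
from exodel.simulate import (  # noqa: E402
    simulate_depth_cohort,
    simulate_gene_models,
    simulate_network,
    simulate_reference_maps,
    simulate_variant_table,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    cfg = study_config(args.seed)
    out = RESULTS / "cohort"
    big = SCRATCH / "cohort"
    out.mkdir(parents=True, exist_ok=True)
    big.mkdir(parents=True, exist_ok=True)

    matrix, truth = simulate_depth_cohort(cfg)
    io.write_depth_tsv(matrix, big / "depth.tsv")
    truth.deletions.to_csv(out / "truth_deletions.tsv", sep="\t", index=False)
    io.write_phenotypes_tsv(truth.phenotypes, out / "phenotypes.tsv")

    genes = simulate_gene_models(cfg)
    io.write_gene_models_bed(genes, out / "genes.bed")

    variants = simulate_variant_table(cfg, genes)
    io.write_vcf(variants, matrix.samples, big / "variants.vcf")

    net = simulate_network(cfg, [g.symbol for g in genes])
    io.write_network_tsv(net, out / "ppin_edges.tsv", out / "ppin_nodes.tsv")

    maps = simulate_reference_maps(cfg, truth)
    for m in maps:
        io.write_refmap_bed(m, out / f"refmap_{m.name}.bed")

    io.dump_yaml_config(cfg, out / "sim_config.yaml")

    n_large = (truth.deletions["end"] - truth.deletions["start"] > 400_000).sum()
    print(f"cohort: {matrix.n_samples} samples x {matrix.n_targets} targets at "
          f"{cfg.depth_mean:.0f}x (seed {args.seed})")
    print(f"phenotypes: {truth.phenotypes.value_counts().to_dict()}")
    print(f"embedded deletions: {len(truth.deletions)} carrier-events over "
          f"{truth.deletions['locus'].nunique()} loci ({n_large} events >400 kb)")
    print(f"gene models: {len(genes)}; variants: {len(variants)}; "
          f"network: {net.n_genes} genes / {net.n_interactions} interactions")
    print(f"wrote small tables to {out}, depth matrix and VCF to {big}")


if __name__ == "__main__":
    main()
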