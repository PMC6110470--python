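#!/usr/bin/env python
"""Gene-set over-representation of the deleted, brain-expressed genes
against a brain-expressed background (one truly enriched set among null
sets), plus a rank-sum comparison of per-gene CNV-tolerance-like scores
between the two case groups."""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS, study_config  # noqa: E402

import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from exodel import io  # noqa: E402
from exodel.enrich import overrep_test, rank_sum_test, set_overlap  # noqa: E402
from exodel.simulate import simulate_gene_sets  # noqa: E402


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    cfg = study_config(args.seed)
    genes = io.read_gene_models(RESULTS / "cohort" / "genes.bed")
    deleted_genes = pd.read_csv(RESULTS / "03_deleted_genes.tsv", sep="\t")

    brain = {g.symbol for g in genes if g.brain_expressed}
    universe = sorted(brain)
    query = sorted(set(deleted_genes["gene"]) & brain)
    sets = simulate_gene_sets(cfg, universe, favoured=set(query))
    io.write_gmt(sets, RESULTS / "06_gene_sets.gmt")

    rows = []
    for gs in sets:
        overlap = set_overlap(set(query), gs)
        res = overrep_test(len(overlap), len(query), len(gs.symbols), len(universe))
        rows.append((gs.name, res.k, res.n, res.K, res.N, res.p_value))
        print(f"  {gs.name}: overlap {res.k}/{res.n} against {res.K}-gene set "
              f"(background {res.N}) -> p = {res.p_value:.4g}")
    table = pd.DataFrame(rows, columns=["set", "k", "n", "K", "N", "p"])
    table.to_csv(RESULTS / "06_enrichment.tsv", sep="\t", index=False,
                 float_format="%.4g")

    # per-gene CNV-tolerance-like scores drawn from one distribution:
    # GGE- vs RE-deleted genes should not separate
    rng = np.random.default_rng(cfg.seed)
    scores = {g: float(rng.normal()) for g in sorted(deleted_genes["gene"].unique())}
    by_pheno = {
        p: [scores[g] for g in grp["gene"].unique()]
        for p, grp in deleted_genes.groupby("phenotype")
    }
    if len(by_pheno) == 2:
        (pa, a), (pb, b) = sorted(by_pheno.items())
        p = rank_sum_test(a, b)
        print(f"tolerance-score rank-sum {pa} (n={len(a)}) vs {pb} (n={len(b)}): "
              f"p = {p:.3f}")
        pd.DataFrame([{"group_a": pa, "n_a": len(a), "group_b": pb, "n_b": len(b),
                       "p": p}]).to_csv(
            RESULTS / "06_tolerance_ranksum.tsv", sep="\t", index=False,
            float_format="%.4g")


if __name__ == "__main__":
    main()
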