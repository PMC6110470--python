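#!/usr/bin/env python
"""Apply the deletion filters: z < -3 with Q_SOME >= 60, then the case-only
screen (absent from controls, <= 2 independent case carriers, <= 1% in every
reference CNV map), and annotate surviving deletions with overlapping genes."""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import CASES, RESULTS, SCRATCH  # noqa: E402

import pandas as pd  # noqa: E402

from exodel import io  # noqa: E402
from exodel.postprocess import (  # noqa: E402
    annotate_genes,
    build_gene_index,
    case_only_filter,
    filter_deletions,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.parse_args()

    calls = io.read_calls_tsv(SCRATCH / "calls_raw.tsv")
    phenotypes = io.read_phenotypes_tsv(RESULTS / "cohort" / "phenotypes.tsv")
    genes = io.read_gene_models(RESULTS / "cohort" / "genes.bed")
    maps = [
        io.read_refmap_bed(p)
        for p in sorted((RESULTS / "cohort").glob("refmap_*.bed"))
    ]

    dels = filter_deletions(calls)
    case_calls = [c for c in dels if phenotypes.get(c.sample) in CASES]
    control_calls = [c for c in dels if phenotypes.get(c.sample) == "CTRL"]
    case_only = case_only_filter(case_calls, control_calls, maps)
    io.write_calls_tsv(dels, SCRATCH / "calls_filtered.tsv")
    io.write_calls_tsv(case_only, RESULTS / "03_case_only.tsv")

    index = build_gene_index(genes)
    rows = []
    for c in case_only:
        for symbol in annotate_genes(c, index):
            rows.append((c.sample, phenotypes.get(c.sample), c.chrom, c.start, c.end,
                         c.end - c.start, round(c.z_mean, 2), c.q_some, symbol))
    gene_table = pd.DataFrame(
        rows, columns=["sample", "phenotype", "chrom", "start", "end", "length",
                       "z_mean", "q_some", "gene"],
    )
    gene_table.to_csv(RESULTS / "03_deleted_genes.tsv", sep="\t", index=False)

    carriers = {c.sample for c in case_only}
    print(f"quality filter: {len(calls)} raw calls -> {len(dels)} deletions "
          f"({len(case_calls)} in cases, {len(control_calls)} in controls)")
    print(f"case-only screen: {len(case_calls)} -> {len(case_only)} deletions "
          f"in {len(carriers)} carriers")
    print(f"deleted genes: {gene_table['gene'].nunique()} distinct symbols "
          f"({RESULTS / '03_deleted_genes.tsv'})")


if __name__ == "__main__":
    main()
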