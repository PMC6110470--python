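"""Shared study configuration for the numbered analysis drivers.

The cohort mirrors a two-phenotype epilepsy exome study after QC: 196
generalized-epilepsy-like (GGE) cases, 194 Rolandic-like (RE) cases and 572
population controls, simulated over 5,000 exome targets at 100x. Embedded
deletions cover the situations the pipeline must distinguish:

* rare case-only loci (1-2 carriers in one case group) that should survive
  every filter and drive the downstream gene-level analyses,
* loci shared with controls (removed by the case-only rule),
* loci planted at >1% frequency in the reference CNV maps (removed by the
  frequency rule),
* large (>400 kb) loci, enriched in cases, that feed the burden test while
  each staying under the 0.5% internal frequency ceiling.
"""

from pathlib import Path

from exodel.simulate import DeletionSpec, RefMapSpec, SimConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

ALL = ("GGE", "RE", "CTRL")
CASES = ("GGE", "RE")


def study_config(seed: int = 1) -> SimConfig:
    deletion_spec = (
        # two case loci planted as common in the reference maps (dropped by
        # the frequency rule); they must come first: the map generator
        # plants the lowest-numbered loci
        DeletionSpec(phenotypes=("GGE",), carrier_fraction=0.01, n_targets=12),
        DeletionSpec(phenotypes=("RE",), carrier_fraction=0.01, n_targets=14),
        # loci shared with controls (dropped by the case-only rule)
        DeletionSpec(phenotypes=ALL, carrier_fraction=0.008, n_targets=12),
        DeletionSpec(phenotypes=ALL, carrier_fraction=0.008, n_targets=16),
        # rare case-only loci: the discovery set
        DeletionSpec(phenotypes=("GGE",), carrier_fraction=0.005, n_targets=10),
        DeletionSpec(phenotypes=("GGE",), carrier_fraction=0.010, n_targets=13),
        DeletionSpec(phenotypes=("GGE",), carrier_fraction=0.005, n_targets=18),
        DeletionSpec(phenotypes=("RE",), carrier_fraction=0.005, n_targets=11),
        DeletionSpec(phenotypes=("RE",), carrier_fraction=0.010, n_targets=15),
        DeletionSpec(phenotypes=("RE",), carrier_fraction=0.005, n_targets=22),
        DeletionSpec(phenotypes=("RE",), carrier_fraction=0.005, n_targets=10),
        # large (>400 kb) loci for the burden analysis: enriched in cases,
        # each rare enough to pass the 0.5% internal frequency ceiling
        DeletionSpec(phenotypes=CASES, carrier_fraction=0.008, n_targets=140),
        DeletionSpec(phenotypes=CASES, carrier_fraction=0.008, n_targets=150),
        DeletionSpec(phenotypes=CASES, carrier_fraction=0.005, n_targets=145),
        DeletionSpec(phenotypes=CASES, carrier_fraction=0.008, n_targets=160),
        DeletionSpec(phenotypes=CASES, carrier_fraction=0.005, n_targets=150),
        DeletionSpec(phenotypes=("CTRL",), carrier_fraction=0.005, n_targets=145),
        DeletionSpec(phenotypes=("CTRL",), carrier_fraction=0.003, n_targets=155),
    )
    return SimConfig(
        n_cases_a=196,
        n_cases_b=194,
        n_controls=572,
        n_targets=5000,
        target_gap_mean=3000.0,  # sparser layout so >400 kb spans ~140 targets
        depth_mean=100.0,
        deletion_spec=deletion_spec,
        refmap_spec=RefMapSpec(n_common_truth_loci=2),
        seed=seed,
    )
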