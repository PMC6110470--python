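"""Synthetic-cohort generator: determinism, calibration, embedded truth."""

import numpy as np
import pytest

from exodel.simulate import (
    DeletionSpec,
    SimConfig,
    simulate_depth_cohort,
    simulate_gene_models,
    simulate_network,
    simulate_reference_maps,
    simulate_variant_table,
)
from exodel.calls import reciprocal_overlap

SMALL = dict(n_cases_a=30, n_cases_b=30, n_controls=60, n_targets=600)


def test_no_deletion_spec_means_empty_truth():
    _, truth = simulate_depth_cohort(SimConfig(**SMALL, seed=5))
    assert len(truth.deletions) == 0


def test_same_seed_reproduces_depth_exactly():
    cfg = SimConfig(**SMALL, seed=11, deletion_spec=(DeletionSpec(carrier_fraction=0.1),))
    m1, t1 = simulate_depth_cohort(cfg)
    m2, t2 = simulate_depth_cohort(cfg)
    np.testing.assert_array_equal(m1.depth, m2.depth)
    assert t1.deletions.equals(t2.deletions)


def test_different_seeds_differ():
    m1, _ = simulate_depth_cohort(SimConfig(**SMALL, seed=1))
    m2, _ = simulate_depth_cohort(SimConfig(**SMALL, seed=2))
    assert not np.array_equal(m1.depth, m2.depth)


def test_deleted_cells_have_half_the_depth_of_non_carriers():
    """Monte-Carlo check of the generator's own expectation at copy ratio 0.5."""
    cfg = SimConfig(
        n_cases_a=100,
        n_cases_b=0,
        n_controls=400,
        n_targets=400,
        seed=7,
        deletion_spec=(
            DeletionSpec(phenotypes=("GGE",), carrier_fraction=0.5, n_targets=20),
        ),
    )
    matrix, truth = simulate_depth_cohort(cfg)
    assert truth.deletions["sample"].nunique() == 50
    r = truth.deletions.iloc[0]
    carriers = set(truth.deletions["sample"])
    idx = {s: i for i, s in enumerate(matrix.samples)}
    car = [idx[s] for s in matrix.samples if s in carriers]
    non = [idx[s] for s in matrix.samples if s not in carriers]
    block = slice(int(r.t0), int(r.t1) + 1)
    ratio = matrix.depth[car, block].mean() / matrix.depth[non, block].mean()
    assert 0.45 <= ratio <= 0.55


def test_depth_moments_match_count_model():
    """Per-cell variance follows mean + mean^2/size within MC tolerance."""
    cfg = SimConfig(
        n_cases_a=0, n_cases_b=0, n_controls=600, n_targets=200, seed=3,
        target_log_sd=0.0, sample_log_sd=0.0, batch_rank=0, batch_sd=0.0,
    )
    matrix, _ = simulate_depth_cohort(cfg)
    mean = matrix.depth.mean()
    var = matrix.depth.var(axis=0).mean()
    assert mean == pytest.approx(cfg.depth_mean, rel=0.02)
    expected_var = cfg.depth_mean + cfg.depth_mean**2 / cfg.depth_dispersion
    assert var == pytest.approx(expected_var, rel=0.1)


def test_oversized_deletion_spec_is_rejected():
    cfg = SimConfig(**SMALL, seed=1, deletion_spec=(DeletionSpec(n_targets=10_000),))
    with pytest.raises(ValueError, match="exceeds"):
        simulate_depth_cohort(cfg)


def test_phenotype_labels_cover_all_samples():
    cfg = SimConfig(**SMALL, seed=1)
    matrix, truth = simulate_depth_cohort(cfg)
    assert list(truth.phenotypes.index) == matrix.samples
    assert truth.phenotypes.value_counts().to_dict() == {
        "CTRL": 60, "GGE": 30, "RE": 30,
    }


class TestVariantTable:
    def test_zero_rate_yields_empty_table(self):
        cfg = SimConfig(**SMALL, seed=2)
        cfg = SimConfig(**SMALL, seed=2, variant_spec=cfg.variant_spec.__class__(per_gene_rate=0.0))
        genes = simulate_gene_models(cfg)
        assert simulate_variant_table(cfg, genes) == []

    def test_seeded_determinism(self):
        cfg = SimConfig(**SMALL, seed=9)
        genes = simulate_gene_models(cfg)
        t1 = simulate_variant_table(cfg, genes)
        t2 = simulate_variant_table(cfg, genes)
        assert [(v.chrom, v.pos, v.ref, v.alts) for v in t1] == [
            (v.chrom, v.pos, v.ref, v.alts) for v in t2
        ]

    def test_effect_fractions_match_spec_within_binomial_error(self):
        from exodel.simulate import VariantSpec

        spec = VariantSpec(
            per_gene_rate=2.0,
            effect_probs=(("stopgain", 0.30), ("missense", 0.70)),
        )
        cfg = SimConfig(
            n_cases_a=5, n_cases_b=5, n_controls=10, n_targets=1600, seed=13,
            variant_spec=spec,
        )
        genes = simulate_gene_models(cfg)
        table = simulate_variant_table(cfg, genes)
        assert len(table) > 700
        frac = sum(v.effect == "stopgain" for v in table) / len(table)
        assert 0.27 <= frac <= 0.33

    def test_empty_gene_models_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            simulate_variant_table(SimConfig(**SMALL, seed=1), [])


class TestNetwork:
    def test_two_genes_degree_one_gives_single_edge(self):
        from exodel.simulate import NetworkSpec

        cfg = SimConfig(**SMALL, seed=4, network_spec=NetworkSpec(n_genes=2, mean_degree=1.0))
        net = simulate_network(cfg, ["A", "B"])
        assert net.n_genes == 2 and net.n_interactions == 1

    def test_full_brain_fraction_flags_every_node(self):
        from exodel.simulate import NetworkSpec

        cfg = SimConfig(
            **SMALL, seed=4,
            network_spec=NetworkSpec(n_genes=50, mean_degree=4.0, brain_expressed_fraction=1.0),
        )
        genes = [f"G{i}" for i in range(50)]
        net = simulate_network(cfg, genes)
        assert net.brain_genes() == set(genes)

    def test_edge_count_matches_mean_degree_expectation(self):
        from exodel.simulate import NetworkSpec

        cfg = SimConfig(
            **SMALL, seed=21,
            network_spec=NetworkSpec(n_genes=2000, mean_degree=10.0),
        )
        net = simulate_network(cfg, [f"G{i}" for i in range(2000)])
        assert 9000 <= net.n_interactions <= 11000  # n*k/2 +- 10%

    def test_excessive_degree_rejected(self):
        from exodel.simulate import NetworkSpec

        with pytest.raises(ValueError):
            NetworkSpec(n_genes=5, mean_degree=5.0)


class TestReferenceMaps:
    def _cohort(self, n_common):
        from exodel.simulate import RefMapSpec

        cfg = SimConfig(
            **SMALL,
            seed=17,
            deletion_spec=tuple(
                DeletionSpec(phenotypes=("GGE", "RE", "CTRL"), carrier_fraction=0.05, n_targets=8)
                for _ in range(6)
            ),
            refmap_spec=RefMapSpec(n_common_truth_loci=n_common),
        )
        _, truth = simulate_depth_cohort(cfg)
        return cfg, truth

    def test_no_common_loci_configured_means_no_common_overlap(self):
        cfg, truth = self._cohort(0)
        maps = simulate_reference_maps(cfg, truth)
        for m in maps:
            for chrom, start, end, freq in m.intervals:
                if freq > 0.01:
                    for r in truth.deletions.itertuples():
                        assert reciprocal_overlap((chrom, start, end), (r.chrom, r.start, r.end)) == 0.0 or freq <= 0.01

    def test_configured_truth_loci_become_common(self):
        cfg, truth = self._cohort(5)
        maps = simulate_reference_maps(cfg, truth)
        loci = truth.deletions.drop_duplicates("locus")
        n_common = 0
        for r in loci.itertuples():
            hit = any(
                freq > 0.01
                and reciprocal_overlap((chrom, start, end), (r.chrom, r.start, r.end)) >= 0.7
                for m in maps
                for chrom, start, end, freq in m.intervals
            )
            n_common += hit
        assert n_common == 5

    def test_seeded_determinism(self):
        cfg, truth = self._cohort(2)
        m1 = simulate_reference_maps(cfg, truth)
        m2 = simulate_reference_maps(cfg, truth)
        assert [m.intervals for m in m1] == [m.intervals for m in m2]
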