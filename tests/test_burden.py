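"""Burden selection, statistics and permutation p-values."""

import numpy as np
import pandas as pd
import pytest

from exodel.burden import (
    BurdenConfig,
    burden_statistics,
    permutation_pvalue,
    select_burden_set,
)
from exodel.calls import CnvCall


def dele(sample, length, start=1_000_000, chrom="chr1"):
    return CnvCall(sample=sample, chrom=chrom, start=start, end=start + length,
                   type="DEL", n_targets=10, z_mean=-4.0, q_some=99)


class TestSelectBurdenSet:
    SAMPLES = [f"S{i}" for i in range(900)]

    def test_exact_threshold_length_dropped(self):
        assert select_burden_set([dele("S0", 400_000)], self.SAMPLES) == []

    def test_rare_large_deletion_retained(self):
        calls = [dele("S0", 500_000)]
        assert select_burden_set(calls, self.SAMPLES) == calls

    def test_common_locus_dropped_entirely(self):
        calls = [dele(f"S{i}", 500_000) for i in range(10)]  # freq 10/900 > 0.5%
        assert select_burden_set(calls, self.SAMPLES) == []

    def test_carrier_counting_uses_reciprocal_overlap(self):
        # same locus with small shifts: every pair still matches at >= 0.7
        calls = [dele(f"S{i}", 500_000, start=1_000_000 + i * 10_000) for i in range(10)]
        assert select_burden_set(calls, self.SAMPLES) == []


class TestBurdenStatistics:
    def test_cases_with_one_call_each(self):
        phen = pd.Series(["case"] * 4 + ["ctrl"] * 4, index=[f"S{i}" for i in range(8)])
        calls = [dele(f"S{i}", 100_000) for i in range(4)]
        stats = burden_statistics(calls, phen)
        assert stats["case"] == {
            "rate_per_person": 1.0,
            "proportion_with_deletion": 1.0,
            "total_length": 100_000.0,
            "average_length": 100_000.0,
        }
        assert stats["ctrl"]["rate_per_person"] == 0.0
        assert stats["ctrl"]["average_length"] == 0.0  # zero-call convention

    def test_two_calls_in_one_of_two_samples(self):
        phen = pd.Series(["g", "g"], index=["A", "B"])
        calls = [dele("A", 100_000), dele("A", 300_000, start=5_000_000)]
        stats = burden_statistics(calls, phen)["g"]
        assert stats["rate_per_person"] == 1.0
        assert stats["proportion_with_deletion"] == 0.5
        assert stats["average_length"] == 200_000.0

    def test_symmetric_groups_agree(self):
        phen = pd.Series(["a"] * 3 + ["b"] * 3, index=[f"S{i}" for i in range(6)])
        calls = [dele("S0", 500_000), dele("S3", 500_000)]
        stats = burden_statistics(calls, phen)
        assert stats["a"] == stats["b"]

    def test_unlabelled_sample_raises(self):
        phen = pd.Series(["a"], index=["S0"])
        with pytest.raises(ValueError, match="phenotype"):
            burden_statistics([dele("S9", 500_000)], phen)


class TestPermutationPvalue:
    def _pheno(self, n_case, n_ctrl):
        return pd.Series(
            [True] * n_case + [False] * n_ctrl,
            index=[f"S{i}" for i in range(n_case + n_ctrl)],
        )

    def test_exhaustive_four_vs_four_gives_one_in_seventy(self):
        """All 4 carriers are cases: only the true labeling reaches the
        observed rate difference, so p = 1 / C(8,4) = 1/70."""
        phen = self._pheno(4, 4)
        calls = [dele(f"S{i}", 500_000) for i in range(4)]
        res = permutation_pvalue(calls, phen)
        assert res.exhaustive
        assert res.p_values["rate_per_person"] == pytest.approx(1 / 70)
        assert res.p_values["proportion_with_deletion"] == pytest.approx(1 / 70)

    def test_identical_groups_are_null(self):
        phen = self._pheno(4, 4)
        calls = [dele("S0", 500_000), dele("S4", 500_000)]
        res = permutation_pvalue(calls, phen)
        for stat, p in res.p_values.items():
            assert p >= 0.5, stat

    def test_seeded_sampling_is_deterministic(self):
        phen = self._pheno(15, 15)
        calls = [dele(f"S{i}", 500_000 + i * 1000) for i in range(6)]
        cfg = BurdenConfig(n_perm=300, seed=42, exhaustive_max_labelings=10)
        r1 = permutation_pvalue(calls, phen, cfg)
        r2 = permutation_pvalue(calls, phen, cfg)
        assert not r1.exhaustive
        assert r1.p_values == r2.p_values

    def test_p_respects_add_one_floor_and_ceiling(self):
        phen = self._pheno(10, 10)
        calls = [dele(f"S{i}", 500_000) for i in range(10)]
        cfg = BurdenConfig(n_perm=100, seed=1, exhaustive_max_labelings=10)
        res = permutation_pvalue(calls, phen, cfg)
        for p in res.p_values.values():
            assert 1 / 101 <= p <= 1.0

    def test_sampled_p_converges_to_exhaustive_p(self):
        """Monte-Carlo p within 3 SE of the exact enumeration value."""
        phen = self._pheno(6, 6)
        calls = [dele(f"S{i}", 500_000 + 10_000 * i) for i in (0, 1, 2, 6)]
        exact = permutation_pvalue(calls, phen, BurdenConfig(n_perm=10))
        assert exact.exhaustive
        n_perm = 4000
        sampled = permutation_pvalue(
            calls, phen, BurdenConfig(n_perm=n_perm, seed=7, exhaustive_max_labelings=10)
        )
        for stat in exact.p_values:
            p_ex = exact.p_values[stat]
            se = np.sqrt(p_ex * (1 - p_ex) / n_perm)
            assert abs(sampled.p_values[stat] - p_ex) <= 3 * se + 1 / n_perm, stat

    def test_single_group_raises(self):
        phen = self._pheno(4, 0)
        with pytest.raises(ValueError, match="case and one control"):
            permutation_pvalue([dele("S0", 500_000)], phen)

    def test_string_labels_require_case_labels(self):
        phen = pd.Series(["GGE", "CTRL"], index=["A", "B"])
        with pytest.raises(ValueError, match="case_labels"):
            permutation_pvalue([dele("A", 500_000)], phen)
        res = permutation_pvalue([dele("A", 500_000)], phen, case_labels={"GGE"})
        assert res.p_values["rate_per_person"] == pytest.approx(0.5)
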