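"""End-to-end orchestration: simulate -> call -> filter -> burden,
classify -> compound-het screen, then over-representation.

Every stage writes its intermediates under the run directory and adds its
input/output counts to the run report, so each stage is replayable in
isolation; a stage failure aborts with the failing stage named while partial
outputs stay on disk.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .burden import BurdenConfig, permutation_pvalue, select_burden_set
from .caller import pca_normalize, sample_coverage_qc
from .enrich import overrep_test, set_overlap
from .hmm import HmmParams, call_cohort
from .network import DeleteriousVariant, build_brain_network, find_comphet_hits
from .postprocess import FilterConfig, annotate_genes, build_gene_index, case_only_filter, filter_deletions
from .simulate import (
    PHENO_CASE_A,
    PHENO_CASE_B,
    PHENO_CONTROL,
    SimConfig,
    simulate_depth_cohort,
    simulate_gene_models,
    simulate_network,
    simulate_reference_maps,
    simulate_variant_table,
)
from .variants import ClassifierConfig, apply_genotype_qc, classify_deleterious, is_rare

logger = logging.getLogger("exodel")

__all__ = ["PipelineConfig", "RunReport", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    hmm: HmmParams = field(default_factory=HmmParams)
    filters: FilterConfig = field(default_factory=FilterConfig)
    burden: BurdenConfig = field(default_factory=BurdenConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    pca_rel_var_threshold: float = 0.7
    run_burden: bool = True
    run_comphet: bool = True
    run_enrichment: bool = True
    out_dir: str = "results/pipeline"


@dataclass
class RunReport:
    seed: int
    counts: dict = field(default_factory=dict)
    excluded_samples: list = field(default_factory=list)
    burden: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    comphet_hits: list = field(default_factory=list)
    config_digest: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True, default=str)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except Exception as err:  # noqa: BLE001 - abort with the stage named
                raise PipelineError(name, err) from err

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.sim.seed)
    report.config_digest = {
        "sim": dataclasses.asdict(config.sim),
        "hmm": dataclasses.asdict(config.hmm),
        "filters": dataclasses.asdict(config.filters),
        "burden": dataclasses.asdict(config.burden),
        "classifier": dataclasses.asdict(config.classifier),
    }

    matrix, truth = _stage("simulate")(simulate_depth_cohort)(config.sim)
    genes = _stage("simulate")(simulate_gene_models)(config.sim)
    io.write_depth_tsv(matrix, out / "depth.tsv")
    report.counts["samples_simulated"] = matrix.n_samples
    report.counts["targets"] = matrix.n_targets
    report.counts["truth_deletions"] = len(truth.deletions)

    def _call():
        qc_matrix, excluded = sample_coverage_qc(matrix)
        norm = pca_normalize(qc_matrix, config.pca_rel_var_threshold)
        return qc_matrix, excluded, norm, call_cohort(norm.samples, norm.z, norm.targets, config.hmm)

    qc_matrix, excluded, norm, calls = _stage("call")(_call)()
    report.excluded_samples = excluded
    report.counts["samples_after_qc"] = qc_matrix.n_samples
    report.counts["calls_raw"] = len(calls)
    io.write_calls_tsv(calls, out / "calls_raw.tsv")

    def _filter():
        dels = filter_deletions(calls, config.filters)
        phenos = truth.phenotypes
        case_calls = [c for c in dels if phenos.get(c.sample) in (PHENO_CASE_A, PHENO_CASE_B)]
        control_calls = [c for c in dels if phenos.get(c.sample) == PHENO_CONTROL]
        maps = simulate_reference_maps(config.sim, truth)
        case_only = case_only_filter(case_calls, control_calls, maps, config.filters)
        return dels, case_calls, control_calls, case_only

    dels, case_calls, control_calls, case_only = _stage("filter")(_filter)()
    report.counts["calls_after_quality_filter"] = len(dels)
    report.counts["case_calls"] = len(case_calls)
    report.counts["control_calls"] = len(control_calls)
    report.counts["case_only_deletions"] = len(case_only)
    io.write_calls_tsv(case_only, out / "case_only.tsv")

    gene_index = build_gene_index(genes)
    deleted_by_sample: dict[str, set[str]] = {}
    for c in case_only:
        deleted_by_sample.setdefault(c.sample, set()).update(annotate_genes(c, gene_index))
    report.counts["deleted_genes"] = len(set().union(*deleted_by_sample.values())) if deleted_by_sample else 0

    if config.run_burden:
        def _burden():
            burden_set = select_burden_set(dels, list(truth.phenotypes.index), config.burden)
            res = permutation_pvalue(
                burden_set,
                truth.phenotypes,
                config.burden,
                case_labels={PHENO_CASE_A, PHENO_CASE_B},
            )
            return burden_set, res

        burden_set, res = _stage("burden")(_burden)()
        report.counts["burden_deletions"] = len(burden_set)
        report.burden = {
            "case": res.case_values,
            "control": res.control_values,
            "p": res.p_values,
            "exhaustive": res.exhaustive,
        }

    variants = _stage("classify")(simulate_variant_table)(config.sim, genes)
    report.counts["variants_simulated"] = len(variants)

    def _classify():
        out_vars = []
        for v in variants:
            v = apply_genotype_qc(v)
            if not is_rare(v, config.classifier):
                continue
            flag, fired = classify_deleterious(v, config.classifier)
            if flag:
                out_vars.append((v, fired))
        return out_vars

    deleterious = _stage("classify")(_classify)()
    report.counts["rare_deleterious_variants"] = len(deleterious)

    if config.run_comphet:
        def _comphet():
            net = simulate_network(config.sim, [g.symbol for g in genes])
            brain = {g.symbol for g in genes if g.brain_expressed}
            brain_net = build_brain_network(net, {g.symbol for g in genes}, brain)
            by_sample: dict[str, list[DeleteriousVariant]] = {}
            for v, _ in deleterious:
                dv_list = [
                    DeleteriousVariant(
                        gene=v.gene,
                        chrom=v.chrom,
                        pos=v.pos,
                        ref=v.ref,
                        alt=v.alts[0],
                        annotation=v.effect,
                    )
                ]
                for s, g in v.genotypes.items():
                    if g.has_alt:
                        by_sample.setdefault(s, []).extend(dv_list)
            return find_comphet_hits(deleted_by_sample, by_sample, brain_net)

        hits = _stage("comphet")(_comphet)()
        report.counts["comphet_hits"] = len(hits)
        report.comphet_hits = [dataclasses.asdict(h) for h in hits]

    if config.run_enrichment:
        def _enrich():
            from .simulate import simulate_gene_sets

            deleted = set().union(*deleted_by_sample.values()) if deleted_by_sample else set()
            brain = {g.symbol for g in genes if g.brain_expressed}
            universe = sorted(brain)
            query = sorted(deleted & brain)
            sets = simulate_gene_sets(config.sim, universe, favoured=set(query))
            results = {}
            for gs in sets:
                overlap = set_overlap(set(query), gs)
                res = overrep_test(len(overlap), len(query), len(gs.symbols), len(universe))
                results[gs.name] = {
                    "k": res.k,
                    "n": res.n,
                    "K": res.K,
                    "N": res.N,
                    "p": res.p_value,
                }
            return results

        report.enrichment = _stage("enrich")(_enrich)()

    report.to_json(out / "report.json")
    return report
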