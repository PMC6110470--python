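"""File-format codecs for every artefact the pipeline reads or writes.

Interval convention: intervals are carried internally as (start, end) with
start 1-based and end exclusive, so length = end - start. BED (0-based
half-open) and GFF3 (1-based fully inclusive) are converted exactly at the
boundary: BED (s, e) <-> internal (s + 1, e + 1); GFF3 (s, e) <-> internal
(s, e + 1).

Every reader raises ``CodecError`` naming the file, line number and the rule
violated on malformed input.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import pysam
import yaml

from .caller import DepthMatrix
from .calls import CnvCall
from .enrich import GeneSet
from .network import InteractionNetwork
from .postprocess import GeneModel, ReferenceCnvMap
from .variants import PREDICTOR_PANEL, Genotype, VariantRecord

__all__ = [
    "CodecError",
    "write_depth_tsv",
    "read_depth_tsv",
    "write_calls_tsv",
    "read_calls_tsv",
    "calls_to_bed",
    "write_refmap_bed",
    "read_refmap_bed",
    "write_gene_models_bed",
    "read_gene_models",
    "write_network_tsv",
    "read_network_tsv",
    "write_gmt",
    "read_gmt",
    "write_vcf",
    "read_vcf",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "load_yaml_config",
    "dump_yaml_config",
]


class CodecError(ValueError):
    def __init__(self, path, line_no: int | None, rule: str):
        where = f"{path}" if line_no is None else f"{path}:{line_no}"
        super().__init__(f"{where}: {rule}")


# ---------------------------------------------------------------- depth TSV


def write_depth_tsv(matrix: DepthMatrix, path) -> None:
    """Sample rows, target columns labelled 'chrom:start-end'."""
    cols = [
        f"{r.chrom}:{r.start}-{r.end}" for r in matrix.targets.itertuples()
    ]
    df = pd.DataFrame(matrix.depth, index=matrix.samples, columns=cols)
    df.index.name = "SAMPLE"
    df.to_csv(path, sep="\t", float_format="%.4g")


def read_depth_tsv(path) -> DepthMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    rows = []
    for i, col in enumerate(df.columns):
        try:
            chrom, span = col.split(":")
            start, end = span.split("-")
            rows.append((chrom, int(start), int(end)))
        except ValueError:
            raise CodecError(path, 1, f"target header {col!r} is not chrom:start-end") from None
    targets = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return DepthMatrix([str(s) for s in df.index], targets, df.to_numpy(dtype=float))


# ------------------------------------------------------- deletion calls TSV

_CALL_COLS = ["SAMPLE", "CNV", "INTERVAL", "KB", "MID_BP", "NUM_TARG", "Q_SOME", "MEAN_Z"]


def write_calls_tsv(calls: Iterable[CnvCall], path) -> None:
    """XCNV-like tab layout; INTERVAL is chrom:start-end in internal coords."""
    with open(path, "w") as fh:
        fh.write("\t".join(_CALL_COLS) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    [
                        c.sample,
                        c.type,
                        f"{c.chrom}:{c.start}-{c.end}",
                        f"{c.length_bp / 1000:.3f}",
                        str((c.start + c.end) // 2),
                        str(c.n_targets),
                        "" if c.q_some is None else str(c.q_some),
                        f"{c.z_mean:.6g}",
                    ]
                )
                + "\n"
            )


def read_calls_tsv(path) -> list[CnvCall]:
    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _CALL_COLS:
            raise CodecError(path, 1, f"expected header {_CALL_COLS}")
        for line_no, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_CALL_COLS):
                raise CodecError(path, line_no, f"expected {len(_CALL_COLS)} columns")
            try:
                chrom, span = parts[2].split(":")
                start, end = (int(x) for x in span.split("-"))
                calls.append(
                    CnvCall(
                        sample=parts[0],
                        chrom=chrom,
                        start=start,
                        end=end,
                        type=parts[1],
                        n_targets=int(parts[5]),
                        z_mean=float(parts[7]),
                        q_some=int(parts[6]) if parts[6] else None,
                    )
                )
            except ValueError as err:
                raise CodecError(path, line_no, f"malformed call record ({err})") from None
    return calls


def calls_to_bed(calls: Iterable[CnvCall], path) -> None:
    """BED representation (0-based half-open) with name sample|type|q_some."""
    with open(path, "w") as fh:
        for c in calls:
            name = f"{c.sample}|{c.type}|{'' if c.q_some is None else c.q_some}"
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end - 1}\t{name}\t{c.z_mean:.4g}\n")


# ----------------------------------------------------- reference CNV maps


def write_refmap_bed(ref_map: ReferenceCnvMap, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, freq in ref_map.intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end - 1}\t{freq:.6g}\n")


def read_refmap_bed(path, name: str | None = None) -> ReferenceCnvMap:
    intervals = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise CodecError(path, line_no, "need chrom, start, end, frequency")
            try:
                intervals.append(
                    (parts[0], int(parts[1]) + 1, int(parts[2]) + 1, float(parts[3]))
                )
            except ValueError as err:
                raise CodecError(path, line_no, f"malformed map interval ({err})") from None
    return ReferenceCnvMap(name=name or Path(path).stem, intervals=intervals)


# ------------------------------------------------------------- gene models


def write_gene_models_bed(genes: list[GeneModel], path) -> None:
    """BED12-style: exons as blocks, brain_expressed as the score column."""
    with open(path, "w") as fh:
        for g in genes:
            exons = g.exons or [(g.start, g.end)]
            sizes = ",".join(str(e - s) for s, e in exons)
            offsets = ",".join(str(s - g.start) for s, _ in exons)
            fh.write(
                f"{g.chrom}\t{g.start - 1}\t{g.end - 1}\t{g.symbol}\t"
                f"{int(g.brain_expressed)}\t+\t{g.start - 1}\t{g.end - 1}\t0\t"
                f"{len(exons)}\t{sizes}\t{offsets}\n"
            )


def _read_gene_models_bed(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise CodecError(path, line_no, "need >= 5 BED columns for a gene model")
            try:
                start, end = int(parts[1]) + 1, int(parts[2]) + 1
                exons = []
                if len(parts) >= 12:
                    sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                    offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
                    exons = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
                genes.append(
                    GeneModel(
                        symbol=parts[3],
                        chrom=parts[0],
                        start=start,
                        end=end,
                        exons=exons,
                        brain_expressed=bool(int(parts[4])),
                    )
                )
            except ValueError as err:
                raise CodecError(path, line_no, f"malformed gene model ({err})") from None
    return genes


def _read_gene_models_gff3(path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise CodecError(path, line_no, "GFF3 requires 9 columns")
            chrom, _, ftype, start, end, _, _, _, attrs = parts
            try:
                start_i, end_i = int(start), int(end) + 1  # 1-based inclusive -> internal
            except ValueError:
                raise CodecError(path, line_no, "start/end must be integers") from None
            fields = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                symbol = fields.get("Name") or fields.get("ID")
                if not symbol:
                    raise CodecError(path, line_no, "gene feature needs Name or ID")
                genes[fields.get("ID", symbol)] = GeneModel(
                    symbol=symbol,
                    chrom=chrom,
                    start=start_i,
                    end=end_i,
                    exons=[],
                    brain_expressed=fields.get("brain_expressed", "0") == "1",
                )
            elif ftype == "exon":
                parent = fields.get("Parent")
                if parent and parent in genes:
                    genes[parent].exons.append((start_i, end_i))
    return list(genes.values())


def read_gene_models(path) -> list[GeneModel]:
    """Auto-detect BED vs GFF3 by file extension."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return _read_gene_models_gff3(path)
    if suffix == ".bed":
        return _read_gene_models_bed(path)
    raise CodecError(path, None, f"unrecognized gene-model extension {suffix!r}")


# ----------------------------------------------------------------- network


def write_network_tsv(net: InteractionNetwork, edges_path, nodes_path) -> None:
    with open(edges_path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u}\t{v}\n")
    with open(nodes_path, "w") as fh:
        fh.write("gene\tbrain_expressed\n")
        for node in sorted(net.graph.nodes):
            fh.write(f"{node}\t{int(net.graph.nodes[node].get('brain_expressed', False))}\n")


def read_network_tsv(edges_path, nodes_path=None) -> InteractionNetwork:
    edges = []
    with open(edges_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise CodecError(edges_path, line_no, "edge lines need two columns")
            edges.append((parts[0], parts[1]))
    brain: set[str] = set()
    net = InteractionNetwork.from_edges(edges)
    if nodes_path is not None:
        with open(nodes_path) as fh:
            header = fh.readline()
            if not header.startswith("gene"):
                raise CodecError(nodes_path, 1, "node table must start with 'gene' header")
            for line_no, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    raise CodecError(nodes_path, line_no, "node lines need two columns")
                net.graph.add_node(parts[0])
                if parts[1] == "1":
                    brain.add(parts[0])
        for node in net.graph.nodes:
            net.graph.nodes[node]["brain_expressed"] = node in brain
    return net


# --------------------------------------------------------------------- GMT


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, "-"] + sorted(gs.symbols)) + "\n")


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise CodecError(path, line_no, "GMT lines need name, description, >=1 gene")
            sets.append(GeneSet.of(parts[0], parts[2:]))
    return sets


# --------------------------------------------------------------------- VCF

_INFO_FLOAT = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "GQ_MEAN",
               "VQSLOD", "ABHet", "HWE_PHRED", "missingness")
_INFO_INT = ("DP",)
_SCORE_FIELDS = ("CADD", "GERP", "PHYLOP", "SIPHY")


def write_vcf(records: list[VariantRecord], samples: list[str], path) -> None:
    """Uncompressed VCF with the pipeline's INFO/FORMAT keys via pysam.

    Samples absent from a record's genotype dict are written as hom-ref with
    nominal quality (the simulator stores carriers sparsely).
    """
    header = pysam.VariantHeader()
    contigs = sorted({r.chrom for r in records})
    for c in contigs:
        header.contigs.add(c)
    for key in _INFO_FLOAT + _SCORE_FIELDS:
        header.info.add(key, 1, "Float", f"{key} site annotation")
    for key in _INFO_INT:
        header.info.add(key, 1, "Integer", f"{key} site annotation")
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("EFFECT", 1, "String", "Functional effect class")
    for p in PREDICTOR_PANEL:
        header.info.add(f"PRED_{p}", 1, "String", f"{p} predictor call")
    dbs = sorted({db for r in records for db in r.afs})
    for db in dbs:
        header.info.add(f"AF_{db}", 1, "Float", f"{db} allele frequency")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alts)):
            rec = vcf.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, *r.alts)
            )
            rec.info["GENE"] = r.gene or "."
            rec.info["EFFECT"] = r.effect
            for key in _INFO_FLOAT:
                if key in r.site:
                    rec.info[key] = float(r.site[key])
            for key in _INFO_INT:
                if key in r.site:
                    rec.info[key] = int(round(r.site[key]))
            for field_name, value in zip(_SCORE_FIELDS, (r.cadd, r.gerp, r.phylop, r.siphy)):
                if value is not None:
                    rec.info[field_name] = float(value)
            for p, call in r.predictors.items():
                rec.info[f"PRED_{p}"] = call
            for db, af in r.afs.items():
                rec.info[f"AF_{db}"] = float(af)
            for s in samples:
                g = r.genotypes.get(s, Genotype(alleles=(0, 0), dp=50, gq=99))
                rec.samples[s]["GT"] = g.alleles
                rec.samples[s]["DP"] = g.dp
                rec.samples[s]["GQ"] = g.gq
            vcf.write(rec)


def read_vcf(path) -> tuple[list[VariantRecord], list[str]]:
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            info = dict(rec.info)
            site = {k: float(info[k]) for k in _INFO_FLOAT + _INFO_INT if k in info}
            predictors = {
                p: str(info.get(f"PRED_{p}", "missing")) for p in PREDICTOR_PANEL
            }
            afs = {
                k[3:]: float(v) for k, v in info.items() if k.startswith("AF_")
            }
            genotypes = {}
            for s in samples:
                sd = rec.samples[s]
                alleles = sd.get("GT")
                if alleles is not None and any(a is None for a in alleles):
                    alleles = None
                genotypes[s] = Genotype(
                    alleles=tuple(alleles) if alleles is not None else None,
                    dp=int(sd.get("DP") or 0),
                    gq=int(sd.get("GQ") or 0),
                )
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    gene=str(info.get("GENE", "")).replace(".", ""),
                    effect=str(info.get("EFFECT", "other")),
                    genotypes=genotypes,
                    site=site,
                    predictors=predictors,
                    cadd=float(info["CADD"]) if "CADD" in info else None,
                    gerp=float(info["GERP"]) if "GERP" in info else None,
                    phylop=float(info["PHYLOP"]) if "PHYLOP" in info else None,
                    siphy=float(info["SIPHY"]) if "SIPHY" in info else None,
                    afs=afs,
                )
            )
    return records, samples


# --------------------------------------------------------------- misc TSV


def write_phenotypes_tsv(phenotypes: pd.Series, path) -> None:
    df = phenotypes.rename("status").rename_axis("sample").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "status"]:
        raise CodecError(path, 1, "phenotype table needs 'sample' and 'status' columns")
    return pd.Series(df["status"].to_numpy(), index=df["sample"], name="phenotype")


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise CodecError(path, None, "config must be a YAML mapping")
    return data


def dump_yaml_config(obj, path) -> None:
    data = asdict(obj) if hasattr(obj, "__dataclass_fields__") else dict(obj)
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(data), fh, sort_keys=True)


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=lambda o: asdict(o) if hasattr(o, "__dataclass_fields__") else list(o) if isinstance(o, (set, tuple, np.ndarray)) else o))
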