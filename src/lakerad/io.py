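"""File formats, reports, and provenance manifests.

FASTQ/FASTA go through Biopython; distance matrices and tables are tab
separated files via pandas; networks are written as GraphML (networkx) and
edge-list TSV; reports are JSON with sorted keys so reruns are
byte-identical.  The VCF writer/reader covers the GT/DP/GQ fields the
pipeline produces and round-trips its own output byte-wise.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotyping import GenotypeCalls, Site
from .rad_assembly import ReadRecord

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "write_vcf",
    "read_vcf",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_json_report",
    "write_network",
    "sha256_file",
    "Manifest",
]


# ---------------------------------------------------------------------------
# FASTQ / FASTA


def read_fastq(path) -> list:
    """Read FASTQ (Phred+33) into ReadRecords; malformed records raise."""
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        records.append(ReadRecord(id=rec.id, sequence=str(rec.seq), qualities=quals))
    return records


def write_fastq(reads, path) -> None:
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in r.qualities]
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# VCF (GT/DP/GQ subset)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=lakerad
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth (ref+alt)">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(calls: GenotypeCalls, path, depth=None, gq=None) -> None:
    """Write calls as VCF 4.2 with GT, and DP/GQ when matrices are given.

    ``depth``/``gq`` are optional (n_individuals, n_sites) arrays; missing
    ones are written as ``.``.
    """
    inds = calls.individuals
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(inds)
            + "\n"
        )
        for j, site in enumerate(calls.sites):
            cells = []
            for i in range(len(inds)):
                gt = _GT_CODE[int(calls.genotypes[i, j])]
                dp = "." if depth is None else str(int(depth[i, j]))
                g = "." if gq is None else str(int(gq[i, j]))
                cells.append(f"{gt}:{dp}:{g}")
            fh.write(
                f"{site.locus_id}\t{site.position + 1}\t.\t{site.ref}\t{site.alt}"
                f"\t.\tPASS\t.\tGT:DP:GQ\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path):
    """Read a GT/DP/GQ VCF back into (GenotypeCalls, depth, gq).

    Malformed data lines raise with the offending line number.
    """
    inds: list = []
    sites: list = []
    geno_rows: list = []
    dp_rows: list = []
    gq_rows: list = []
    gt_inv = {v: k for k, v in _GT_CODE.items()}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                inds = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            if len(fields) != 9 + len(inds):
                raise ValueError(f"{path}:{ln}: expected {9 + len(inds)} columns")
            chrom, pos, _, ref, alt = fields[:5]
            try:
                sites.append(Site(chrom, int(pos) - 1, ref, alt))
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: bad POS field") from e
            gts, dps, gqs = [], [], []
            for cell in fields[9:]:
                parts = cell.split(":")
                gts.append(gt_inv.get(parts[0], -1))
                dps.append(
                    int(parts[1]) if len(parts) > 1 and parts[1] != "." else -1
                )
                gqs.append(
                    int(parts[2]) if len(parts) > 2 and parts[2] != "." else -1
                )
            geno_rows.append(gts)
            dp_rows.append(dps)
            gq_rows.append(gqs)
    geno = (
        np.asarray(geno_rows, dtype=np.int8).T
        if geno_rows
        else np.zeros((len(inds), 0), dtype=np.int8)
    )
    dp = np.asarray(dp_rows, dtype=int).T if dp_rows else np.zeros((len(inds), 0), int)
    gq = np.asarray(gq_rows, dtype=int).T if gq_rows else np.zeros((len(inds), 0), int)
    site_depth = np.where(dp >= 0, dp, 0).sum(axis=0)
    calls = GenotypeCalls(
        individuals=inds, sites=sites, genotypes=geno, site_depth=site_depth
    )
    return calls, dp, gq


# ---------------------------------------------------------------------------
# tables, reports, networks


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="label")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="label")


def write_json_report(report: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")


def write_network(network, graphml_path=None, edgelist_path=None) -> None:
    """Write a MigrationNetwork as GraphML and/or edge-list TSV."""
    if graphml_path is not None:
        import networkx as nx

        nx.write_graphml(network.to_networkx(), str(graphml_path))
    if edgelist_path is not None:
        rows = [
            {
                "source": s,
                "target": t,
                "weight": w,
                "support": float(network.support.loc[s, t]),
            }
            for s, t, w in network.edges
        ]
        pd.DataFrame(rows, columns=["source", "target", "weight", "support"]).to_csv(
            edgelist_path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# provenance


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Per-stage record of seeds, thresholds, and artifact checksums."""

    def __init__(self) -> None:
        self.stages: dict = {}

    def record(self, stage: str, seed, params: dict, outputs) -> None:
        self.stages[stage] = {
            "seed": seed,
            "params": params,
            "outputs": {Path(p).name: sha256_file(p) for p in outputs},
        }

    def write(self, path) -> None:
        write_json_report({"stages": self.stages}, path)
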