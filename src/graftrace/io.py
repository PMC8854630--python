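"""Readers and writers for the pipeline's on-disk formats.

FASTA/FASTQ go through Biopython with gzip-transparent handles.  GFF3 is
written 1-based inclusive per the standard and converted to the package's
0-based half-open exon intervals on read; the conversion is involutive.
Tables are plain TSV via pandas.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import GeneModel, ReadBatch, Variant


def open_maybe_gzip(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ----------------------------------------------------------------------
# FASTA


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    with open_maybe_gzip(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    with open_maybe_gzip(path, "rt") as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


# ----------------------------------------------------------------------
# FASTQ (paired, _1/_2 suffix convention)


def write_fastq_pair(batch: ReadBatch, prefix) -> tuple[Path, Path]:
    """Write mates to ``<prefix>_1.fastq[.gz]`` and ``<prefix>_2.fastq[.gz]``.

    Qualities are constant 'I' (Phred 40): the pipeline ignores base
    qualities, they are recorded for FASTQ validity only.
    """
    prefix = Path(prefix)
    suffix = ".fastq.gz" if prefix.name.endswith(".gz") else ".fastq"
    if prefix.name.endswith(".gz"):
        prefix = prefix.with_name(prefix.name[:-3])
    paths = (prefix.parent / f"{prefix.name}_1{suffix}",
             prefix.parent / f"{prefix.name}_2{suffix}")
    qual = "I"
    for path, mates in zip(paths, (batch.mate1, batch.mate2)):
        with open_maybe_gzip(path, "wt") as fh:
            for rid, seq in zip(batch.ids, mates):
                fh.write(f"@{rid}\n{seq}\n+\n{qual * len(seq)}\n")
    return paths


def read_fastq_pair(path1, path2, sample=None) -> ReadBatch:
    """Load a mate pair of FASTQ files into a ReadBatch (no truth labels)."""
    def load(path):
        with open_maybe_gzip(path, "rt") as fh:
            return [(rec.id, str(rec.seq))
                    for rec in SeqIO.parse(fh, "fastq")]

    r1, r2 = load(path1), load(path2)
    if [i for i, _ in r1] != [i for i, _ in r2]:
        raise ValueError("mate files disagree on read ids or order")
    ids = [i for i, _ in r1]
    m1 = [s for _, s in r1]
    m2 = [s for _, s in r2]
    if not m1:
        raise ValueError("empty FASTQ input")
    L = len(m1[0])
    n = len(ids)
    return ReadBatch(ids, m1, m2, truth_gene=["?"] * n,
                     truth_genome=["?"] * n, read_length=L, sample=sample)


# ----------------------------------------------------------------------
# GFF3


def write_gff3(genes: list[GeneModel], path, source: str = "graftrace") -> None:
    with open_maybe_gzip(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gs = min(s for s, _ in g.exons) + 1
            ge = max(e for _, e in g.exons)
            attrs = f"ID={g.gene_id};origin={g.origin}"
            fh.write(f"{g.contig}\t{source}\tgene\t{gs}\t{ge}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.contig}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.exon{i};"
                         f"Parent={g.gene_id}\n")


def read_gff3(path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    with open_maybe_gzip(path, "rt") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            (contig, _, ftype, start, end, _, strand, _,
             attrs) = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1)
                          for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                genes[fields["ID"]] = {
                    "contig": contig, "strand": strand,
                    "origin": fields.get("origin", "scion"), "exons": []}
            elif ftype == "exon":
                parent = fields["Parent"]
                # GFF3 is 1-based inclusive; memory is 0-based half-open
                genes[parent]["exons"].append((int(start) - 1, int(end)))
    return [GeneModel(gene_id=gid, contig=g["contig"], strand=g["strand"],
                      exons=tuple(sorted(g["exons"])), origin=g["origin"])
            for gid, g in genes.items()]


# ----------------------------------------------------------------------
# TSV tables


def write_variants_tsv(variants: list, path) -> None:
    rows = []
    for v in variants:
        row = {"contig": v.contig, "pos0": v.pos, "ref": v.ref, "alt": v.alt}
        if hasattr(v, "depth"):
            row["depth"] = v.depth
            row["fraction"] = round(v.fraction, 4)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[Variant]:
    df = pd.read_csv(path, sep="\t")
    return [Variant(r.contig, int(r.pos0), r.ref, r.alt)
            for r in df.itertuples()]


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_mobile_calls_tsv(calls, path) -> None:
    """One row per gene, status in {mobile, false_positive}."""
    rows = [{"gene_id": g, "support": c, "status": "mobile"}
            for g, c in sorted(calls.final.items())]
    rows += [{"gene_id": g, "support": 0, "status": "false_positive"}
             for g in sorted(calls.false_positives)]
    pd.DataFrame(rows, columns=["gene_id", "support", "status"]).to_csv(
        path, sep="\t", index=False)
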