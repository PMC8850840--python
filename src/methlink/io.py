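"""Readers and writers for the pipeline's external formats.

Conventions: every TSV uses 1-based inclusive coordinates; BED files alone
are 0-based half-open (converted at the boundary).  The cytosine report
dialect is the one common bisulfite callers emit: one file per sample with
columns chrom, pos (1-based), strand, context, count_methylated,
count_unmethylated.  Gene models are read from GFF3/GTF (via gffutils) or
BED12; with multiple transcripts per gene the longest one defines
TSS/TTS/exons (most-upstream-TSS selectable).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GeneModel

__all__ = [
    "FormatError",
    "read_cytosine_report",
    "read_cytosine_reports",
    "write_cytosine_reports",
    "read_gene_models",
    "write_gff3",
    "write_bed12",
    "read_fasta",
    "write_fasta",
    "read_counts",
    "read_design",
    "read_term_map",
    "read_ct_table",
]

REPORT_COLUMNS = ["chrom", "pos", "strand", "context", "count_methylated", "count_unmethylated"]


class FormatError(ValueError):
    """Malformed external file; the message names the offending line."""


def read_cytosine_report(path) -> pd.DataFrame:
    """One sample's cytosine report -> validated frame with REPORT_COLUMNS."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if list(df.columns) != REPORT_COLUMNS:
        if df.shape[1] == len(REPORT_COLUMNS):
            # headerless: documented column order
            df = pd.read_csv(path, sep="\t", header=None, names=REPORT_COLUMNS,
                             dtype={"chrom": str})
        else:
            raise FormatError(
                f"{path}: expected columns {REPORT_COLUMNS}, got {list(df.columns)}"
            )
    bad = df.index[(df["count_methylated"] < 0) | (df["count_unmethylated"] < 0)]
    if len(bad):
        raise FormatError(f"{path}: negative count at line {int(bad[0]) + 2}")
    bad = df.index[~df["strand"].isin(["+", "-"])]
    if len(bad):
        raise FormatError(f"{path}: bad strand at line {int(bad[0]) + 2}")
    bad = df.index[~df["context"].isin(["CG", "CHG", "CHH"])]
    if len(bad):
        raise FormatError(f"{path}: bad context at line {int(bad[0]) + 2}")
    dup = df.duplicated(["chrom", "pos", "strand"])
    if dup.any():
        raise FormatError(
            f"{path}: duplicate site at line {int(df.index[dup][0]) + 2}"
        )
    return df


def read_cytosine_reports(paths: dict) -> pd.DataFrame:
    """Merge per-sample reports into the wide site table (m_<s>/u_<s> columns)."""
    merged = None
    for sample in paths:
        df = read_cytosine_report(paths[sample])
        df = df.rename(
            columns={"count_methylated": f"m_{sample}", "count_unmethylated": f"u_{sample}"}
        )
        if merged is None:
            merged = df
        else:
            merged = merged.merge(
                df, on=["chrom", "pos", "strand", "context"], how="outer"
            )
    merged = merged.fillna(0)
    for c in merged.columns:
        if c.startswith(("m_", "u_")):
            merged[c] = merged[c].astype(np.int32)
    return merged.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(
        drop=True
    )


def write_cytosine_reports(sites: pd.DataFrame, out_dir, samples=None) -> dict:
    """One report TSV per sample; returns sample -> path."""
    from .methylome import sample_columns

    os.makedirs(out_dir, exist_ok=True)
    samples = samples or sample_columns(sites)
    paths = {}
    for s in samples:
        df = sites[["chrom", "pos", "strand", "context"]].copy()
        df["count_methylated"] = sites[f"m_{s}"]
        df["count_unmethylated"] = sites[f"u_{s}"]
        path = os.path.join(out_dir, f"{s}.cytosine_report.tsv")
        df.to_csv(path, sep="\t", index=False)
        paths[s] = path
    return paths


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path):
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(genes, path, source: str = "methlink"):
    """Genes as GFF3 (gene + mRNA + exon rows, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            a, b = g.start, g.end
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{a}\t{b}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\t{source}\tmRNA\t{a}\t{b}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for i, (ea, eb) in enumerate(sorted(g.exons)):
                fh.write(
                    f"{g.chrom}\t{source}\texon\t{ea}\t{eb}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.t1.e{i + 1};Parent={g.gene_id}.t1\n"
                )


def write_bed12(genes, path):
    """BED12 mirror of the gene models (0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            exons = sorted(g.exons) or [(g.start, g.end)]
            starts = [a - g.start for a, _ in exons]
            sizes = [b - a + 1 for a, b in exons]
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            g.chrom, g.start - 1, g.end, g.gene_id, 0, g.strand,
                            g.start - 1, g.end, "0,0,0", len(exons),
                            ",".join(map(str, sizes)) + ",",
                            ",".join(map(str, starts)) + ",",
                        ],
                    )
                )
                + "\n"
            )


def _gene_from_span(gene_id, chrom, strand, start, end, exons):
    if strand == "+":
        tss, tts = start, end
    elif strand == "-":
        tss, tts = end, start
    else:
        raise FormatError(f"{gene_id}: unknown strand symbol {strand!r}")
    return GeneModel(gene_id, chrom, strand, tss, tts, exons)


def read_gene_models(path, transcript_rule: str = "longest") -> list:
    """Gene models from GFF3/GTF or BED12, one transcript per gene.

    ``transcript_rule``: 'longest' (default) or 'most_upstream' TSS.
    """
    path = str(path)
    if path.endswith((".bed", ".bed12")):
        return _read_bed12(path)
    return _read_gff(path, transcript_rule)


def _read_bed12(path) -> list:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{ln}: BED12 needs 12 columns, got {len(f)}")
            chrom, start0, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
            starts = [int(x) for x in f[11].rstrip(",").split(",") if x]
            exons = [
                (start0 + s + 1, start0 + s + sz) for s, sz in zip(starts, sizes)
            ]
            genes.append(_gene_from_span(name, chrom, strand, start0 + 1, end, exons))
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def _read_gff(path, transcript_rule: str) -> list:
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        transcripts = list(db.children(g, featuretype=("mRNA", "transcript"), level=1))
        if transcripts:
            if transcript_rule == "longest":
                tx = max(transcripts, key=lambda t: (t.end - t.start, t.id))
            elif transcript_rule == "most_upstream":
                if g.strand == "+":
                    tx = min(transcripts, key=lambda t: (t.start, t.id))
                else:
                    tx = max(transcripts, key=lambda t: (t.end, t.id))
            else:
                raise ValueError(f"unknown transcript rule {transcript_rule!r}")
            exons = [(e.start, e.end) for e in db.children(tx, featuretype="exon")]
            span = (tx.start, tx.end)
        else:
            exons = [(e.start, e.end) for e in db.children(g, featuretype="exon")]
            span = (g.start, g.end)
        genes.append(
            _gene_from_span(g.id, g.seqid, g.strand, span[0], span[1], sorted(exons))
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count matrix (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df < 0).any().any():
        raise FormatError(f"{path}: negative count")
    df.index.name = "gene_id"
    return df


def read_design(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "group"} <= set(df.columns):
        raise FormatError(f"{path}: design needs 'sample' and 'group' columns")
    return df.set_index("sample")["group"]


def read_term_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"term_id", "gene_id"} <= set(df.columns):
        raise FormatError(f"{path}: term map needs 'term_id' and 'gene_id' columns")
    return df


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    req = {"sample", "group", "gene", "ct_target", "ct_reference"}
    if not req <= set(df.columns):
        raise FormatError(f"{path}: Ct table needs columns {sorted(req)}")
    return df
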