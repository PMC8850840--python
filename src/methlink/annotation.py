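"""Genomic elements, DMR annotation and DMR-related genes (DMGs).

The promoter is the 3,000 bp immediately upstream of the transcription
start site (strand-aware); the gene body runs from the TSS to the
transcriptional termination site.  Two distinct overlap rules are used on
purpose: element *distribution* assigns every DMR exactly one label by
midpoint containment with a fixed precedence (promoter > exon > intron >
gene body > distal intergenic), while DMR -> gene mapping uses any >= 1 bp
interval overlap with a gene's promoter or body, so one DMR can support
several genes and one gene can be hit in both elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "ElementMap",
    "MalformedGeneError",
    "UnknownContigError",
    "derive_elements",
    "assign_dmr_element",
    "map_dmrs_to_genes",
    "venn_counts",
]

PROMOTER_BP = 3000
ELEMENT_PRECEDENCE = ("promoter", "exon", "intron", "gene_body", "distal_intergenic")


class MalformedGeneError(ValueError):
    """TSS/TTS ordering inconsistent with the declared strand."""


class UnknownContigError(KeyError):
    """A DMR sits on a chromosome absent from the element map."""


@dataclass
class GeneModel:
    """Strand-aware gene coordinates (all 1-based inclusive).

    ``tss``/``tts`` are in transcription orientation: on '+' tss <= tts, on
    '-' tss >= tts.  ``exons`` are (start, end) pairs in forward genomic
    coordinates.  For multi-transcript inputs the reader has already picked
    one transcript (longest by default).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: list = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in "+-":
            raise MalformedGeneError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.strand == "+" and self.tss > self.tts:
            raise MalformedGeneError(f"{self.gene_id}: tss > tts on + strand")
        if self.strand == "-" and self.tss < self.tts:
            raise MalformedGeneError(f"{self.gene_id}: tss < tts on - strand")

    @property
    def start(self) -> int:
        return min(self.tss, self.tts)

    @property
    def end(self) -> int:
        return max(self.tss, self.tts)

    def promoter(self, chrom_size: int | None = None, promoter_bp: int = PROMOTER_BP):
        """Strand-aware promoter interval, clipped to the chromosome."""
        if self.strand == "+":
            lo, hi = self.tss - promoter_bp, self.tss - 1
        else:
            lo, hi = self.tss + 1, self.tss + promoter_bp
        lo = max(lo, 1)
        if chrom_size is not None:
            hi = min(hi, chrom_size)
        if hi < lo:
            return None
        return lo, hi


@dataclass
class ElementMap:
    """Per-chromosome interval trees of labelled gene elements.

    Trees use half-open integer intervals [start, end + 1) carrying
    (gene_id, tss) payloads; ``chrom_sizes`` defines the distal-intergenic
    complement implicitly (anything hit by no promoter or gene body).
    """

    promoter: dict
    gene_body: dict
    exon: dict
    intron: dict
    chrom_sizes: dict
    promoter_bp: int = PROMOTER_BP

    def trees_for(self, label: str) -> dict:
        return getattr(self, label)


def _add(trees: dict, chrom: str, lo: int, hi: int, payload):
    if hi < lo:
        return
    trees.setdefault(chrom, IntervalTree()).addi(lo, hi + 1, payload)


def derive_elements(genes, chrom_sizes: dict, promoter_bp: int = PROMOTER_BP) -> ElementMap:
    """Derive promoter / gene-body / exon / intron intervals for every gene.

    Overlapping genes yield overlapping elements; no exclusivity between
    genes is imposed.  Promoters are clipped at chromosome edges.
    """
    em = ElementMap({}, {}, {}, {}, dict(chrom_sizes), promoter_bp)
    for g in genes:
        size = chrom_sizes.get(g.chrom)
        payload = (g.gene_id, g.tss)
        prom = g.promoter(size, promoter_bp)
        if prom is not None:
            _add(em.promoter, g.chrom, prom[0], prom[1], payload)
        _add(em.gene_body, g.chrom, g.start, g.end, payload)
        exons = sorted((int(a), int(b)) for a, b in g.exons)
        for a, b in exons:
            _add(em.exon, g.chrom, a, b, payload)
        # introns: gene body minus exons
        cursor = g.start
        for a, b in exons:
            if a > cursor:
                _add(em.intron, g.chrom, cursor, a - 1, payload)
            cursor = max(cursor, b + 1)
        if not exons:
            cursor = g.end + 1  # no exon annotation: whole body stays gene_body
        if cursor <= g.end:
            _add(em.intron, g.chrom, cursor, g.end, payload)
    return em


def _best_hit(hits, midpoint):
    """Deterministic tie-break: nearest TSS, then lexicographic gene_id."""
    return min(hits, key=lambda iv: (abs(midpoint - iv.data[1]), iv.data[0]))


def assign_dmr_element(dmr_row, elements: ElementMap, promoter_bp: int | None = None):
    """Single element label for one DMR by midpoint containment + precedence.

    ``dmr_row`` needs ``chrom``, ``start``, ``end`` (1-based inclusive).
    Returns (label, gene_id or None).
    """
    chrom = dmr_row["chrom"]
    if chrom not in elements.chrom_sizes:
        raise UnknownContigError(chrom)
    midpoint = (int(dmr_row["start"]) + int(dmr_row["end"])) // 2
    for label in ("promoter", "exon", "intron", "gene_body"):
        trees = elements.trees_for(label)
        tree = trees.get(chrom)
        if tree is None:
            continue
        hits = tree[midpoint]
        if hits:
            best = _best_hit(hits, midpoint)
            return label, best.data[0]
    return "distal_intergenic", None


def annotate_dmrs(dmrs: pd.DataFrame, elements: ElementMap) -> pd.DataFrame:
    """Vector convenience: element label + host gene for every DMR row."""
    labels, gene_ids = [], []
    for _, row in dmrs.iterrows():
        lab, gid = assign_dmr_element(row, elements)
        labels.append(lab)
        gene_ids.append(gid)
    out = dmrs.copy()
    out["element"] = labels
    out["element_gene"] = gene_ids
    return out


def map_dmrs_to_genes(dmrs: pd.DataFrame, elements: ElementMap) -> pd.DataFrame:
    """DMR-related genes: >= 1 bp overlap with a promoter or gene body.

    Returns one row per (gene, overlapped element class) aggregate:
    gene_id, n_dmrs, promoter/body hit flags, partition in
    {promoter_only, body_only, both}, and direction_summary in
    {hyper, hypo, both} (both when hyper and hypo DMRs co-occur on the
    gene).  A DMR may contribute to several genes.
    """
    per_gene: dict[str, dict] = {}
    for idx, row in dmrs.iterrows():
        chrom = row["chrom"]
        lo, hi = int(row["start"]), int(row["end"]) + 1
        for element in ("promoter", "gene_body"):
            tree = elements.trees_for(element).get(chrom)
            if tree is None:
                continue
            for iv in tree.overlap(lo, hi):
                gid = iv.data[0]
                rec = per_gene.setdefault(
                    gid, {"dmr_idx": set(), "elements": set(), "directions": set()}
                )
                rec["dmr_idx"].add(idx)
                rec["elements"].add(element)
                d = row.get("direction", "")
                if d:
                    rec["directions"].add(d)
    rows = []
    for gid in sorted(per_gene):
        rec = per_gene[gid]
        has_p = "promoter" in rec["elements"]
        has_b = "gene_body" in rec["elements"]
        partition = "both" if (has_p and has_b) else ("promoter_only" if has_p else "body_only")
        dirs = rec["directions"]
        if dirs == {"hyper"}:
            dsum = "hyper"
        elif dirs == {"hypo"}:
            dsum = "hypo"
        elif dirs:
            dsum = "both"
        else:
            dsum = ""
        rows.append(
            {
                "gene_id": gid,
                "n_dmrs": len(rec["dmr_idx"]),
                "in_promoter": has_p,
                "in_gene_body": has_b,
                "partition": partition,
                "direction_summary": dsum,
                "dmr_rows": sorted(rec["dmr_idx"]),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "n_dmrs", "in_promoter", "in_gene_body",
            "partition", "direction_summary", "dmr_rows",
        ],
    )
    out.attrs["comparison"] = dmrs.attrs.get("comparison", "")
    return out


def venn_counts(named_sets: dict) -> dict:
    """Cardinality of every membership region of 2-3 named sets.

    Keys are tuples of the member set names (e.g. ('A',), ('A', 'B')); the
    region counted is 'in exactly these sets and no others'.  Counts sum to
    the size of the union.
    """
    names = list(named_sets)
    if len(names) < 2:
        raise ValueError("need at least two sets")
    sets = {k: set(v) for k, v in named_sets.items()}
    universe = set().union(*sets.values())
    out = {}
    from itertools import combinations

    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(universe)
            for n in combo:
                inside &= sets[n]
            for n in names:
                if n not in combo:
                    inside -= sets[n]
            out[combo] = len(inside)
    return out
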