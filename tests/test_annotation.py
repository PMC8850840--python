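"""Element derivation, DMR labelling and DMR-to-gene mapping."""

import numpy as np
import pandas as pd
import pytest

from methlink.annotation import (
    GeneModel,
    MalformedGeneError,
    UnknownContigError,
    assign_dmr_element,
    derive_elements,
    map_dmrs_to_genes,
    venn_counts,
)

SIZES = {"chr1": 100_000}


def gene(gid="g1", chrom="chr1", strand="+", tss=10_000, tts=15_000, exons=None):
    return GeneModel(gid, chrom, strand, tss, tts, exons or [])


def dmr_row(chrom="chr1", start=1, end=10, direction="hyper", context="CG"):
    return {"chrom": chrom, "start": start, "end": end,
            "direction": direction, "context": context}


def test_promoter_plus_strand():
    g = gene(strand="+", tss=10_000, tts=15_000)
    assert g.promoter(100_000) == (7_000, 9_999)


def test_promoter_minus_strand_mirror():
    g = gene(strand="-", tss=10_000, tts=5_000)
    assert g.promoter(100_000) == (10_001, 13_000)


def test_promoter_clipped_at_chromosome_edge():
    g = gene(strand="+", tss=1_000, tts=2_000)
    assert g.promoter(100_000) == (1, 999)


def test_malformed_gene_rejected():
    with pytest.raises(MalformedGeneError):
        GeneModel("bad", "chr1", "+", 500, 100)
    with pytest.raises(MalformedGeneError):
        GeneModel("bad", "chr1", "-", 100, 500)


def test_precedence_promoter_over_intron():
    g1 = gene("g1", tss=10_000, tts=15_000)  # promoter 7000-9999
    g2 = gene("g2", tss=5_000, tts=12_000, exons=[(5_000, 6_000), (11_000, 12_000)])
    elements = derive_elements([g1, g2], SIZES)
    # midpoint 8000: inside g1's promoter and g2's intron
    label, gid = assign_dmr_element(dmr_row(start=7_900, end=8_100), elements)
    assert (label, gid) == ("promoter", "g1")


def test_distal_intergenic_fallback_and_unknown_contig():
    elements = derive_elements([gene()], SIZES)
    label, gid = assign_dmr_element(dmr_row(start=50_000, end=50_100), elements)
    assert (label, gid) == ("distal_intergenic", None)
    with pytest.raises(UnknownContigError):
        assign_dmr_element(dmr_row(chrom="chrX"), elements)


def test_tie_breaks_are_deterministic():
    # two genes, promoters overlapping, midpoint equidistant from both TSS
    ga = gene("gb", strand="+", tss=10_000, tts=12_000)
    gb = gene("ga", strand="-", tss=8_000, tts=7_000)  # promoter 8001-11000
    elements = derive_elements([ga, gb], SIZES)
    label, gid = assign_dmr_element(dmr_row(start=8_999, end=9_001), elements)
    assert label == "promoter"
    assert gid == "ga"  # equal TSS distance (1000): lexicographic gene_id


def test_every_dmr_gets_exactly_one_label(small_sim):
    genes = small_sim["genes"]
    sizes = {c: len(s) for c, s in small_sim["reference"].items()}
    elements = derive_elements(genes, sizes)
    rng = np.random.default_rng(0)
    n = 200
    starts = rng.integers(1, sizes["chr1"] - 500, size=n)
    labels = []
    for s in starts:
        label, _ = assign_dmr_element(dmr_row(start=int(s), end=int(s) + 200), elements)
        labels.append(label)
    assert len(labels) == n
    assert set(labels) <= {"promoter", "exon", "intron", "gene_body", "distal_intergenic"}


def brute_force_dmg(dmrs, genes, promoter_bp=3000):
    """All-pairs >= 1 bp overlap oracle for DMR -> gene mapping."""
    hits = {}
    for _, row in dmrs.iterrows():
        for g in genes:
            prom = g.promoter(None, promoter_bp)
            intervals = {"promoter": prom, "gene_body": (g.start, g.end)}
            for element, iv in intervals.items():
                if iv is None or g.chrom != row["chrom"]:
                    continue
                lo, hi = iv
                if row["start"] <= hi and row["end"] >= lo:
                    hits.setdefault(g.gene_id, set()).add(element)
    return hits


def test_dmg_mapping_matches_brute_force(small_sim, rng):
    genes = small_sim["genes"]
    sizes = {c: len(s) for c, s in small_sim["reference"].items()}
    elements = derive_elements(genes, sizes)
    starts = rng.integers(1, sizes["chr1"] - 2000, size=300)
    dmrs = pd.DataFrame(
        [dmr_row(start=int(s), end=int(s) + int(rng.integers(50, 1500))) for s in starts]
    )
    got = map_dmrs_to_genes(dmrs, elements)
    oracle = brute_force_dmg(dmrs, genes)
    assert set(got["gene_id"]) == set(oracle)
    for _, row in got.iterrows():
        els = oracle[row["gene_id"]]
        assert row["in_promoter"] == ("promoter" in els)
        assert row["in_gene_body"] == ("gene_body" in els)


def test_direction_summary_both():
    g = gene("g1", tss=10_000, tts=15_000)
    elements = derive_elements([g], SIZES)
    dmrs = pd.DataFrame(
        [
            dmr_row(start=8_000, end=8_200, direction="hyper"),
            dmr_row(start=11_000, end=11_200, direction="hypo"),
        ]
    )
    out = map_dmrs_to_genes(dmrs, elements)
    assert len(out) == 1
    assert out.iloc[0]["direction_summary"] == "both"
    assert out.iloc[0]["partition"] == "both"


def test_boundary_spanning_dmr_counts_both_elements():
    g = gene("g1", tss=10_000, tts=15_000)
    elements = derive_elements([g], SIZES)
    dmrs = pd.DataFrame([dmr_row(start=9_900, end=10_100)])
    out = map_dmrs_to_genes(dmrs, elements)
    assert out.iloc[0]["partition"] == "both"


def test_gene_without_overlap_absent():
    g = gene("g1", tss=10_000, tts=15_000)
    elements = derive_elements([g], SIZES)
    out = map_dmrs_to_genes(pd.DataFrame([dmr_row(start=50_000, end=50_100)]), elements)
    assert len(out) == 0


def test_venn_counts():
    out = venn_counts({"A": {"g1", "g2"}, "B": {"g2"}, "C": {"g2", "g3"}})
    assert out[("A", "B", "C")] == 1
    assert out[("A",)] == 1
    assert out[("C",)] == 1
    assert sum(out.values()) == 3  # |union|
    disjoint = venn_counts({"A": {1}, "B": {2}})
    assert disjoint[("A", "B")] == 0
    same = venn_counts({"A": {1, 2}, "B": {1, 2}, "C": {1, 2}})
    assert same[("A", "B", "C")] == 2 and sum(same.values()) == 2


def test_strand_symmetry_of_elements():
    """Mirroring the genome maps promoters onto mirrored promoters."""
    L = 50_000
    fwd = gene("g", strand="+", tss=20_000, tts=25_000)
    # mirrored coordinates: x -> L + 1 - x, strand flipped
    rev = gene("g", strand="-", tss=L + 1 - 20_000, tts=L + 1 - 25_000)
    pf = fwd.promoter(L)
    pr = rev.promoter(L)
    assert (L + 1 - pr[1], L + 1 - pr[0]) == pf
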