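"""Generator contracts: determinism, moments of planted effects, null structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from methlink.methylome import pooled_counts
from methlink.simulate import (
    DegPlant,
    InfeasiblePlantError,
    InvalidConfigError,
    SimConfig,
    auto_plant_dmrs,
    generate_reference,
    simulate_bsp_clones,
    simulate_expression,
    simulate_methylome,
)


def test_seeded_determinism_byte_identical():
    cfg = SimConfig(seed=1, chrom_length=50_000, n_genes=5)
    a = generate_reference(cfg)
    b = generate_reference(cfg)
    assert a[0] == b[0]
    assert [(g.gene_id, g.tss, g.tts, tuple(g.exons)) for g in a[1]] == [
        (g.gene_id, g.tss, g.tts, tuple(g.exons)) for g in b[1]
    ]
    sa, _ = simulate_methylome(cfg, *a)
    sb, _ = simulate_methylome(cfg, *b)
    pd.testing.assert_frame_equal(sa, sb)


def test_seed_sensitivity():
    a = generate_reference(SimConfig(seed=1, chrom_length=50_000, n_genes=0))
    b = generate_reference(SimConfig(seed=2, chrom_length=50_000, n_genes=0))
    assert a[0]["chr1"] != b[0]["chr1"]


def test_zero_genes_is_valid():
    ref, genes = generate_reference(SimConfig(seed=3, chrom_length=50_000, n_genes=0))
    assert genes == [] and len(ref["chr1"]) == 50_000


def test_invalid_configs_rejected():
    with pytest.raises(InvalidConfigError):
        SimConfig(chrom_length=-5)
    with pytest.raises(InvalidConfigError):
        SimConfig(dispersion=0.0)
    with pytest.raises(InvalidConfigError):
        SimConfig(cg_baseline=1.5)
    with pytest.raises(InvalidConfigError):
        SimConfig(groups=(("A", 1), ("B", 3)))
    with pytest.raises(InvalidConfigError):
        SimConfig(coupling_strength=0.5)
    with pytest.raises(InvalidConfigError):
        generate_reference(SimConfig(chrom_length=19_000))


def test_gene_models_well_formed(small_sim):
    for g in small_sim["genes"]:
        assert len(g.exons) >= 1
        lo = min(a for a, _ in g.exons)
        hi = max(b for _, b in g.exons)
        assert g.start <= lo and hi <= g.end
        if g.strand == "+":
            assert g.tss <= g.tts
        else:
            assert g.tss >= g.tts


def test_planted_delta_recovered_in_pooled_moments():
    cfg0 = SimConfig(seed=5, chrom_length=400_000, n_genes=0)
    ref, genes = generate_reference(cfg0)
    plants = auto_plant_dmrs(cfg0, ref, genes, n=6, delta=0.4, min_sites=8)
    cfg = SimConfig(seed=5, chrom_length=400_000, n_genes=0, planted_dmrs=plants)
    sites, truth = simulate_methylome(cfg, ref, genes)
    design = cfg.design
    for plant in plants:
        sel = (
            (sites["chrom"] == plant.chrom)
            & (sites["pos"] >= plant.start)
            & (sites["pos"] <= plant.end)
            & (sites["context"].astype(str) == plant.context)
        )
        sub = sites[sel]
        m_a, u_a = pooled_counts(sub, design.index[design == plant.comparison[0]])
        m_b, u_b = pooled_counts(sub, design.index[design == plant.comparison[1]])
        diff = m_a.sum() / (m_a + u_a).sum() - m_b.sum() / (m_b + u_b).sum()
        assert diff == pytest.approx(plant.delta, abs=0.08)


def test_infeasible_plant_detected():
    cfg = SimConfig(seed=6, chrom_length=50_000, n_genes=0)
    ref, genes = generate_reference(cfg)
    from methlink.simulate import DmrPlant

    bad = DmrPlant(chrom="chr1", start=1, end=2, context="CG", delta=0.4)
    with pytest.raises(InfeasiblePlantError):
        simulate_methylome(
            SimConfig(seed=6, chrom_length=50_000, n_genes=0, planted_dmrs=(bad,)),
            ref,
            genes,
        )


def test_plant_level_overflow_rejected():
    cfg = SimConfig(seed=6, chrom_length=100_000, n_genes=0)
    ref, genes = generate_reference(cfg)
    from methlink.simulate import DmrPlant

    # delta +0.4 on the 0.70 CG background without a base override
    chains = auto_plant_dmrs(cfg, ref, genes, n=1, delta=-0.4)
    plant = DmrPlant(
        chrom=chains[0].chrom, start=chains[0].start, end=chains[0].end,
        context="CG", delta=0.4,
    )
    with pytest.raises(InvalidConfigError):
        simulate_methylome(
            SimConfig(seed=6, chrom_length=100_000, n_genes=0, planted_dmrs=(plant,)),
            ref,
            genes,
        )


def test_genomewide_cg_level_near_baseline():
    # law of large numbers on the beta-binomial: >= 1e5 CG sites
    cfg = SimConfig(seed=8, chrom_length=1_500_000, n_genes=0)
    ref, genes = generate_reference(cfg)
    sites, _ = simulate_methylome(cfg, ref, genes)
    cg = sites[sites["context"] == "CG"]
    assert len(cg) >= 1e5
    m, u = pooled_counts(cg, cfg.samples)
    assert 0.68 <= m.sum() / (m.sum() + u.sum()) <= 0.72


def test_null_sites_exchangeable_across_groups(small_sim):
    # no plants, coupling 0: group pooled levels agree closely
    sites = small_sim["sites"]
    cfg = small_sim["config"]
    design = cfg.design
    levels = []
    for grp in ("HPBB", "LPBB"):
        m, u = pooled_counts(sites, design.index[design == grp])
        levels.append(m.sum() / (m.sum() + u.sum()))
    assert abs(levels[0] - levels[1]) < 0.01


def test_planted_log2fc_recovered():
    cfg0 = SimConfig(seed=9, chrom_length=200_000, n_genes=60)
    ref, genes = generate_reference(cfg0)
    plants = tuple(
        DegPlant(genes[i].gene_id, log2fc=2.0, comparison=("LPBB", "HPBB"))
        for i in range(10)
    )
    cfg = SimConfig(seed=9, chrom_length=200_000, n_genes=60, planted_degs=plants)
    prom = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes],
         **{grp: 0.5 for grp, _ in cfg.groups}}
    )
    counts, lengths, truth = simulate_expression(cfg, genes, prom)
    design = cfg.design
    A = counts[design.index[design == "LPBB"]].mean(axis=1)
    B = counts[design.index[design == "HPBB"]].mean(axis=1)
    # per-gene ratios carry sd ~0.4 from the negative-binomial draw at
    # 3 replicates; check each within 3 sigma and the median tightly
    for p in plants:
        ratio = np.log2((A[p.gene_id] + 1) / (B[p.gene_id] + 1))
        assert ratio == pytest.approx(2.0, abs=1.2)
    med = np.median(
        [np.log2((A[p.gene_id] + 1) / (B[p.gene_id] + 1)) for p in plants]
    )
    assert med == pytest.approx(2.0, abs=0.5)


def test_negative_coupling_induces_negative_correlation():
    cfg = SimConfig(
        seed=10, chrom_length=200_000, n_genes=600, coupling_strength=-2.0
    )
    ref, genes = generate_reference(SimConfig(seed=10, chrom_length=200_000, n_genes=600))
    rng = np.random.default_rng(0)
    prom = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            **{grp: rng.beta(3, 2, size=len(genes)) for grp, _ in cfg.groups},
        }
    )
    # same promoter methylation in all groups, varied across genes
    for grp, _ in cfg.groups[1:]:
        prom[grp] = prom[cfg.groups[0][0]]
    counts, _, _ = simulate_expression(cfg, genes, prom)
    mean_expr = counts.mean(axis=1)
    rho = sps.spearmanr(prom.set_index("gene_id")["HPBB"], mean_expr).statistic
    assert rho < -0.2


def test_null_expression_exchangeable():
    cfg = SimConfig(seed=12, chrom_length=100_000, n_genes=80)
    ref, genes = generate_reference(cfg)
    prom = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], **{g_: 0.5 for g_, _ in cfg.groups}}
    )
    counts, _, _ = simulate_expression(cfg, genes, prom)
    # no group structure: Welch p-values roughly uniform, few below 0.05
    from methlink.transcriptome import de_test

    res = de_test(counts, cfg.design, ("LPBB", "HPBB"))
    frac = (res["p_value"] < 0.05).mean()
    assert frac < 0.15


def test_bsp_clone_matrix():
    assert simulate_bsp_clones(1.0, 5, 4, seed=1).all()
    assert not simulate_bsp_clones(0.0, 5, 4, seed=1).any()
    m = simulate_bsp_clones(0.5, 20, 10, seed=2)
    assert m.shape == (10, 20)
    assert 0.3 <= m.mean() <= 0.7
    with pytest.raises(InvalidConfigError):
        simulate_bsp_clones(1.5, 5, 5)
    with pytest.raises(InvalidConfigError):
        simulate_bsp_clones(0.5, 0, 5)


def test_truth_table_enumerates_plants():
    cfg0 = SimConfig(seed=13, chrom_length=200_000, n_genes=10)
    ref, genes = generate_reference(cfg0)
    plants = auto_plant_dmrs(cfg0, ref, genes, n=4, delta=0.4)
    cfg = SimConfig(seed=13, chrom_length=200_000, n_genes=10, planted_dmrs=plants)
    _, truth = simulate_methylome(cfg, ref, genes)
    assert len(truth.true_dmrs) == 4
    assert set(truth.true_dmrs["direction"]) == {"hyper", "hypo"}
    assert (truth.true_dmrs["n_sites"] >= 4).all()
    # regions are disjoint within the context
    iv = truth.true_dmrs.sort_values("start")
    assert (iv["start"].to_numpy()[1:] > iv["end"].to_numpy()[:-1]).all()
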