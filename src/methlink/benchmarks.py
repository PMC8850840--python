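"""Calibration and recovery benchmarks on ground-truthed simulations.

These scenarios measure the operating characteristics of the callers under
the generator's study conditions: false-call rates under the null, recall
and direction accuracy on planted differentially methylated regions,
recall and observed false-discovery rate on planted differentially
expressed genes, and sign recovery of the promoter methylation-expression
coupling.  They are used both by the test suite and by the reproduction
script.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .dmr import call_dmrs
from .integration import (
    STRATA,
    expression_strata,
    gene_tss_methylation,
    intersect_dmg_deg,
    profile_correlation,
    tss_profile,
)
from .annotation import derive_elements, map_dmrs_to_genes
from .simulate import (
    DegPlant,
    SimConfig,
    auto_plant_dmrs,
    generate_reference,
    simulate_expression,
    simulate_methylome,
)
from .transcriptome import compute_fpkm, de_analysis

__all__ = [
    "null_calibration",
    "planted_dmr_recovery",
    "planted_deg_recovery",
    "integration_recovery",
]

COMPARISON = ("LPBB", "HPBB")


def null_calibration(
    seed: int = 0,
    n_seeds: int = 20,
    chrom_length: int = 5_000_000,
    n_genes: int = 150,
) -> dict:
    """No plants, zero coupling: how often do the callers fire anyway?

    The reference genome is generated once; each repetition redraws every
    count with a fresh seed.  Returns the mean fraction of candidate
    regions called DMR and the mean fraction of genes at q < 0.05.
    """
    base = SimConfig(seed=seed, chrom_length=chrom_length, n_genes=n_genes)
    reference, genes = generate_reference(base)
    dmr_fracs, deg_fracs, n_regions = [], [], 0
    for rep in range(n_seeds):
        cfg = dataclasses.replace(base, seed=seed + 1000 + rep)
        sites, truth = simulate_methylome(cfg, reference, genes)
        dmrs, cand = call_dmrs(sites, cfg.design, COMPARISON, return_candidates=True)
        dmr_fracs.append(len(dmrs) / len(cand))
        n_regions += len(cand)
        counts, lengths, _ = simulate_expression(
            cfg, genes, truth.promoter_methylation, truth
        )
        de = de_analysis(counts, cfg.design, COMPARISON)
        deg_fracs.append((de["q_value"] < 0.05).mean())
    return {
        "mean_dmr_fraction": float(np.mean(dmr_fracs)),
        "mean_deg_q05_fraction": float(np.mean(deg_fracs)),
        "n_seeds": n_seeds,
        "n_candidate_regions": n_regions,
        "n_genes": n_genes * n_seeds,
    }


def planted_dmr_recovery(
    seed: int = 0,
    n_plants: int = 200,
    delta: float = 0.4,
    min_sites: int = 5,
    chrom_length: int = 5_000_000,
) -> dict:
    """Recall and direction accuracy on planted CG DMRs (|delta| = 0.4)."""
    base = SimConfig(seed=seed, chrom_length=chrom_length, n_genes=0)
    reference, genes = generate_reference(base)
    plants = auto_plant_dmrs(
        base, reference, genes, n=n_plants, delta=delta,
        comparison=COMPARISON, min_sites=min_sites,
    )
    cfg = dataclasses.replace(base, planted_dmrs=plants)
    sites, truth = simulate_methylome(cfg, reference, genes)
    dmrs = call_dmrs(sites, cfg.design, COMPARISON)

    recovered = 0
    correct_direction = 0
    for plant in plants:
        hits = dmrs[
            (dmrs["chrom"] == plant.chrom)
            & (dmrs["start"] <= plant.end)
            & (dmrs["end"] >= plant.start)
            & (dmrs["context"].astype(str) == plant.context)
        ]
        if len(hits):
            recovered += 1
            if (hits["direction"] == plant.direction).all():
                correct_direction += 1
    return {
        "recall": recovered / n_plants,
        "direction_accuracy": correct_direction / recovered if recovered else float("nan"),
        "n_plants": n_plants,
        "n_called": int(len(dmrs)),
    }


def planted_deg_recovery(
    seed: int = 0,
    n_plants: int = 200,
    n_genes: int = 1000,
    log2fc: float = 2.0,
) -> dict:
    """Recall and observed FDR on planted DEGs (|log2fc| = 2, 3 vs 3)."""
    cfg0 = SimConfig(seed=seed, chrom_length=200_000, n_genes=n_genes)
    _, genes = generate_reference(cfg0)
    rng = np.random.default_rng(seed + 17)
    pick = rng.choice(len(genes), size=n_plants, replace=False)
    plants = tuple(
        DegPlant(
            genes[i].gene_id,
            log2fc=log2fc if j % 2 == 0 else -log2fc,
            comparison=COMPARISON,
        )
        for j, i in enumerate(sorted(pick))
    )
    cfg = dataclasses.replace(cfg0, planted_degs=plants)
    prom = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], **{g_: 0.5 for g_, _ in cfg.groups}}
    )
    counts, lengths, truth = simulate_expression(cfg, genes, prom)
    de = de_analysis(counts, cfg.design, COMPARISON)
    truth_dir = {p.gene_id: p.direction for p in plants}
    called = de[de["status"] != "ns"]
    true_pos = sum(
        1 for g, row in called.iterrows() if truth_dir.get(g) == row["status"]
    )
    recovered = sum(
        1 for g, d in truth_dir.items() if de.loc[g, "status"] == d
    )
    n_called = len(called)
    false_calls = sum(1 for g in called.index if g not in truth_dir)
    return {
        "recall": recovered / n_plants,
        "observed_fdr": false_calls / n_called if n_called else 0.0,
        "n_plants": n_plants,
        "n_called": n_called,
        "n_true_positive": true_pos,
    }


def integration_recovery(
    seed: int = 0,
    chrom_length: int = 1_500_000,
    n_genes: int = 400,
    n_planted: int = 40,
    coupling: float = -2.0,
) -> dict:
    """Sign recovery of the promoter methylation-expression coupling.

    Plants promoter-hyper DMRs on ``n_planted`` genes together with matching
    down-regulation, simulates with strong negative coupling, and measures:
    the Spearman correlation between TSS +/- 2 kb CG methylation and
    expression (with permutation p), the gap between the highest and lowest
    expression strata's promoter-side profiles, and how many planted genes
    surface as hyper-down integration records.
    """
    base = SimConfig(
        seed=seed, chrom_length=chrom_length, n_genes=n_genes,
        coupling_strength=coupling,
    )
    reference, genes = generate_reference(base)
    plants = auto_plant_dmrs(
        base, reference, genes, n=n_planted, delta=0.4, comparison=COMPARISON,
        min_sites=4, within_promoters=True, directions=("hyper",),
    )
    deg_plants = tuple(
        DegPlant(p.target_gene, log2fc=-2.0, comparison=COMPARISON)
        for p in plants
    )
    cfg = dataclasses.replace(base, planted_dmrs=plants, planted_degs=deg_plants)
    sites, truth = simulate_methylome(cfg, reference, genes)
    counts, lengths, truth = simulate_expression(
        cfg, genes, truth.promoter_methylation, truth
    )
    design = cfg.design
    samples_a = list(design.index[design == COMPARISON[0]])

    fpkm = compute_fpkm(counts, lengths)
    mean_a = fpkm[samples_a].mean(axis=1)
    strata = expression_strata(mean_a)
    meth = gene_tss_methylation(sites, genes, samples_a)
    corr = profile_correlation(meth, mean_a, strata=strata, seed=seed)

    profile = tss_profile(sites, genes, strata, samples_a)
    upstream = profile[profile["bin_end"] <= 0]
    prom_means = {
        s: upstream.loc[upstream["stratum"] == s, "mean_level"].mean() for s in STRATA
    }

    thresholds = None
    dmrs = call_dmrs(sites, design, COMPARISON)
    sizes = {c: len(s) for c, s in reference.items()}
    elements = derive_elements(genes, sizes)
    dmgs = map_dmrs_to_genes(dmrs, elements)
    de = de_analysis(counts, design, COMPARISON)
    degs_called = de[de["status"] != "ns"]
    degs_called.attrs["comparison"] = " vs ".join(COMPARISON)
    dmgs.attrs["comparison"] = " vs ".join(COMPARISON)
    records = intersect_dmg_deg(dmgs, degs_called, " vs ".join(COMPARISON))
    hyper_down = records[records["category"] == "hyper-down"]
    targets = {p.target_gene for p in plants}
    return {
        "spearman_rho": corr["spearman_rho"],
        "p_permutation": corr["p_permutation"],
        "anti_monotone": corr["anti_monotone"],
        "promoter_level_highest": prom_means["highest"],
        "promoter_level_lowest": prom_means["lowest"],
        "n_hyper_down": int(len(hyper_down)),
        "planted_recovered_hyper_down": int(len(targets & set(hyper_down["gene_id"]))),
        "n_planted": n_planted,
        "n_genes": n_genes,
    }
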