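"""Synthetic WGBS + RNA-seq data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for a three-genotype sheep-ovary design (HPBB, LPBB, LPB+; three
replicate ewes each): hyper-methylated CG context (baseline ~0.70 pooled
level), near-zero CHG/CHH (~0.006), beta-binomial read counts per cytosine
over Poisson coverage, negative-binomial gene expression, and an optional
negative coupling between a gene's promoter CG methylation and its
expression log-mean.  Differentially methylated regions and differentially
expressed genes can be planted with known effect size and direction, and
every non-null feature is enumerated in a truth table so recall and
false-discovery behaviour of the callers are measurable.

Simulation starts at per-cytosine counts: there is no read-level model, no
bisulfite conversion error and no alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .dmr import build_candidate_regions
from .methylome import genome_cytosine_contexts

__all__ = [
    "SimConfig",
    "DmrPlant",
    "DegPlant",
    "TruthTable",
    "InvalidConfigError",
    "InfeasiblePlantError",
    "generate_reference",
    "simulate_methylome",
    "simulate_expression",
    "simulate_bsp_clones",
    "auto_plant_dmrs",
    "simulate_term_map",
    "default_design",
]


class InvalidConfigError(ValueError):
    """A configuration value is outside its admissible range."""


class InfeasiblePlantError(ValueError):
    """A planted region cannot host the requested effect."""


@dataclass(frozen=True)
class DmrPlant:
    """A planted differential-methylation effect.

    The level of every ``context`` site in [start, end] is shifted by
    ``delta`` in the first-named group of ``comparison``; ``base_level``
    optionally overrides the background level of the region in all groups
    so the shifted level stays inside [0, 1].
    """

    chrom: str
    start: int
    end: int
    context: str = "CG"
    delta: float = 0.4
    comparison: tuple = ("LPBB", "HPBB")
    base_level: float | None = None
    target_gene: str | None = None

    @property
    def direction(self) -> str:
        return "hyper" if self.delta > 0 else "hypo"


@dataclass(frozen=True)
class DegPlant:
    """A planted expression effect: group A's mean is scaled by 2**log2fc."""

    gene_id: str
    log2fc: float
    comparison: tuple = ("LPBB", "HPBB")

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


@dataclass
class SimConfig:
    """Study-condition knobs of the generator.

    Defaults mirror the study design (3 groups x 3 replicates) and the
    magnitude regime of real ovary methylomes: CG pooled level ~0.70,
    CHG/CHH ~0.006, ~30x coverage, beta-binomial overdispersion 0.1,
    negative-binomial size 10.  ``coupling_strength`` (log2 units per unit
    of promoter methylation, <= 0) links promoter CG methylation to
    expression; ``promoter_level_sd`` gives genes heterogeneous promoter
    baselines for that coupling to act on.
    """

    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 2_000_000
    n_genes: int = 150
    groups: tuple = (("HPBB", 3), ("LPBB", 3), ("LPB+", 3))
    mean_coverage: float = 30.0
    cg_baseline: float = 0.70
    chh_chg_baseline: float = 0.006
    dispersion: float = 0.1
    gc_content: float = 0.42
    promoter_level_sd: float = 0.15
    promoter_bp: int = 3000
    expr_log2_mean: float = 7.0
    expr_log2_sd: float = 1.0
    nb_size: float = 10.0
    coupling_strength: float = 0.0
    gene_body_coupling: float = 0.0  # off by default
    planted_dmrs: tuple = ()
    planted_degs: tuple = ()
    max_gap: int = 300
    window_span: int = 1000

    def __post_init__(self):
        if self.n_chroms <= 0 or self.chrom_length <= 0 or self.n_genes < 0:
            raise InvalidConfigError("chromosome/gene counts must be positive")
        for frac, name in [
            (self.cg_baseline, "cg_baseline"),
            (self.chh_chg_baseline, "chh_chg_baseline"),
            (self.gc_content, "gc_content"),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.dispersion < 1.0:
            raise InvalidConfigError("dispersion must lie in (0, 1)")
        if self.nb_size <= 0:
            raise InvalidConfigError("nb_size must be positive")
        if self.mean_coverage <= 0:
            raise InvalidConfigError("mean_coverage must be positive")
        if self.coupling_strength > 0 or self.gene_body_coupling > 0:
            raise InvalidConfigError("coupling strengths must be <= 0")
        if any(n < 2 for _, n in self.groups):
            raise InvalidConfigError("every group needs >= 2 replicates")

    @property
    def samples(self) -> list[str]:
        return [f"{g}_{i + 1}" for g, n in self.groups for i in range(n)]

    @property
    def design(self) -> pd.Series:
        return pd.Series(
            {f"{g}_{i + 1}": g for g, n in self.groups for i in range(n)},
            name="group",
        ).rename_axis("sample")


def default_design(config: SimConfig | None = None) -> pd.Series:
    return (config or SimConfig()).design


def _stream_rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, salt]))


# fixed salts per stream keep the generator deterministic across processes
# (hash() of str is randomised per interpreter)
_SALTS = {
    "reference": 11,
    "genes": 13,
    "methylome": 17,
    "expression": 19,
    "bsp": 23,
    "terms": 29,
    "plants": 31,
}


def generate_reference(config: SimConfig):
    """Simulate chromosome sequences and strand-balanced gene models.

    Bases are i.i.d. with ``gc_content``; genes are placed uniformly with
    2-6 exons, alternating-ish strands, overlaps permitted.  Returns
    (dict chrom -> sequence string, list of GeneModel).
    """
    if config.chrom_length < 20_000:
        raise InvalidConfigError("chrom_length must be >= 20 kb")
    rng = _stream_rng(config.seed, _SALTS["reference"])
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    chroms = {}
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in range(config.n_chroms):
        idx = rng.choice(4, size=config.chrom_length, p=probs)
        chroms[f"chr{i + 1}"] = alphabet[idx].tobytes().decode("ascii")

    grng = _stream_rng(config.seed, _SALTS["genes"])
    genes = []
    names = sorted(chroms)
    for j in range(config.n_genes):
        chrom = names[j % len(names)]
        L = len(chroms[chrom])
        length = int(grng.integers(2_000, 8_001))
        start = int(grng.integers(config.promoter_bp + 1, L - length - config.promoter_bp))
        end = start + length - 1
        strand = "+" if grng.random() < 0.5 else "-"
        n_ex = int(grng.integers(2, 7))
        cuts = np.sort(grng.choice(np.arange(1, length - 1), size=2 * n_ex - 2, replace=False))
        bounds = np.concatenate([[0], cuts, [length - 1]])
        exons = [
            (start + int(bounds[2 * k]), start + int(bounds[2 * k + 1]))
            for k in range(n_ex)
        ]
        tss, tts = (start, end) if strand == "+" else (end, start)
        genes.append(
            GeneModel(f"gene{j + 1:05d}", chrom, strand, tss, tts, exons)
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return chroms, genes


@dataclass
class TruthTable:
    """Exact enumeration of every non-null simulated feature."""

    true_dmrs: pd.DataFrame = field(default_factory=pd.DataFrame)
    true_degs: pd.DataFrame = field(default_factory=pd.DataFrame)
    promoter_methylation: pd.DataFrame = field(default_factory=pd.DataFrame)


def _promoter_interval(gene: GeneModel, promoter_bp: int):
    iv = gene.promoter(None, promoter_bp)
    return iv if iv is not None else (1, 0)


def auto_plant_dmrs(
    config: SimConfig,
    reference: dict,
    genes,
    n: int,
    delta: float = 0.4,
    context: str = "CG",
    comparison: tuple = ("LPBB", "HPBB"),
    min_sites: int = 5,
    within_promoters: bool = False,
    directions=("hyper", "hypo"),
) -> tuple[DmrPlant, ...]:
    """Pick ``n`` plantable regions deterministically from the reference.

    Regions are maximal same-context site chains built with the caller's own
    gap/span rule, so each plant coincides with one candidate region.  The
    region background level is overridden where needed to keep the shifted
    level inside [0, 1] (hyper plants on a 0.70 background would otherwise
    overflow).  With ``within_promoters`` only chains fully inside a gene
    promoter are used and the host gene is recorded.
    """
    rng = _stream_rng(config.seed, _SALTS["plants"])
    site_frames = []
    for chrom in sorted(reference):
        ctx = genome_cytosine_contexts(reference[chrom])
        ctx = ctx[ctx["context"] == context].copy()
        ctx.insert(0, "chrom", chrom)
        site_frames.append(ctx)
    sites = pd.concat(site_frames, ignore_index=True)
    chains = build_candidate_regions(
        sites, max_gap=config.max_gap, window_span=config.window_span
    )
    chains = chains[chains["n_sites"] >= min_sites]

    if within_promoters:
        keep, hosts = [], []
        proms = []
        for g in genes:
            lo, hi = _promoter_interval(g, config.promoter_bp)
            proms.append((g.chrom, lo, hi, g.gene_id))
        for i, row in chains.iterrows():
            for chrom, lo, hi, gid in proms:
                if row["chrom"] == chrom and row["start"] >= lo and row["end"] <= hi:
                    keep.append(i)
                    hosts.append(gid)
                    break
        chains = chains.loc[keep].copy()
        chains["host"] = hosts
        # one plant per gene at most
        chains = chains.drop_duplicates("host")
    if len(chains) < n:
        raise InfeasiblePlantError(
            f"only {len(chains)} plantable chains with >= {min_sites} {context} sites"
        )
    pick = rng.choice(len(chains), size=n, replace=False)
    pick.sort()
    plants = []
    for j, (_, row) in enumerate(chains.iloc[pick].iterrows()):
        direction = directions[j % len(directions)]
        d = abs(delta) if direction == "hyper" else -abs(delta)
        base = config.cg_baseline if context == "CG" else config.chh_chg_baseline
        base_level = None
        if not 0.0 <= base + d <= 1.0:
            # centre the pair of group levels inside [0, 1]
            base_level = float(np.clip(base, max(0.0, -d), min(1.0, 1.0 - d)))
        plants.append(
            DmrPlant(
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                context=context,
                delta=d,
                comparison=tuple(comparison),
                base_level=base_level,
                target_gene=row.get("host") if within_promoters else None,
            )
        )
    return tuple(plants)


def simulate_methylome(config: SimConfig, reference: dict, genes):
    """Draw the per-cytosine count table and its truth table.

    Every cytosine gets a true level per group: CG sites use the genome
    baseline, except promoter CG sites which use their gene's own
    Beta-distributed promoter level; CHG/CHH sites use the low baseline.
    Planted regions shift the first-named comparison group by delta.
    Counts per sample: coverage ~ Poisson(mean_coverage), methylated ~
    Binomial(coverage, Beta(level, dispersion)) — i.e. beta-binomial with
    the between-replicate overdispersion on the beta draw.
    """
    frames = []
    for chrom in sorted(reference):
        ctx = genome_cytosine_contexts(reference[chrom])
        ctx.insert(0, "chrom", chrom)
        frames.append(ctx)
    sites = pd.concat(frames, ignore_index=True)
    sites = sites.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(
        drop=True
    )

    rng = _stream_rng(config.seed, _SALTS["methylome"])
    n = len(sites)
    is_cg = (sites["context"] == "CG").to_numpy()
    base = np.where(is_cg, config.cg_baseline, config.chh_chg_baseline)

    pos_arr = sites["pos"].to_numpy()
    chrom_arr = sites["chrom"].to_numpy()
    bounds = {}
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        bounds[chrom] = (int(idx[0]), int(idx[-1]) + 1)

    def _span(chrom, lo, hi):
        """Global row slice of sites on chrom with lo <= pos <= hi."""
        if chrom not in bounds:
            return 0, 0
        i0, i1 = bounds[chrom]
        a = i0 + int(np.searchsorted(pos_arr[i0:i1], lo, side="left"))
        b = i0 + int(np.searchsorted(pos_arr[i0:i1], hi, side="right"))
        return a, b

    # per-gene promoter baselines (shared across groups): Beta with mean
    # cg_baseline and sd promoter_level_sd
    mu, sd = config.cg_baseline, config.promoter_level_sd
    var = min(sd**2, mu * (1 - mu) * 0.99)
    conc = mu * (1 - mu) / var - 1 if var > 0 else None
    prom_levels = {}
    for g in genes:
        prom_levels[g.gene_id] = (
            float(rng.beta(mu * conc, (1 - mu) * conc)) if conc else mu
        )
        lo, hi = _promoter_interval(g, config.promoter_bp)
        a, b = _span(g.chrom, lo, hi)
        seg = base[a:b]
        seg[is_cg[a:b]] = prom_levels[g.gene_id]

    group_names = [g for g, _ in config.groups]
    level = {g: base.copy() for g in group_names}

    ctx_full = sites["context"].astype(str).to_numpy()
    truth_rows = []
    for plant in config.planted_dmrs:
        if plant.context not in ("CG", "CHG", "CHH"):
            raise InvalidConfigError(f"unknown context {plant.context!r}")
        a_grp, b_grp = plant.comparison
        for g in (a_grp, b_grp):
            if g not in group_names:
                raise InvalidConfigError(f"comparison group {g!r} not simulated")
        a, b = _span(plant.chrom, plant.start, plant.end)
        sel = np.zeros(n, dtype=bool)
        sel[a:b] = ctx_full[a:b] == plant.context
        n_sites = int(sel.sum())
        if n_sites < 3:
            raise InfeasiblePlantError(
                f"planted region {plant.chrom}:{plant.start}-{plant.end} has "
                f"{n_sites} {plant.context} sites (< 3)"
            )
        region_base = plant.base_level
        if region_base is not None:
            for g in group_names:
                level[g] = np.where(sel, region_base, level[g])
        ref_level = region_base if region_base is not None else float(base[sel].mean())
        shifted = ref_level + plant.delta
        if not 0.0 <= shifted <= 1.0:
            raise InvalidConfigError(
                f"plant at {plant.chrom}:{plant.start}-{plant.end} pushes level "
                f"to {shifted:.3f}, outside [0, 1]"
            )
        level[a_grp] = np.where(sel, level[a_grp] + plant.delta, level[a_grp])
        truth_rows.append(
            {
                "chrom": plant.chrom,
                "start": plant.start,
                "end": plant.end,
                "context": plant.context,
                "delta": plant.delta,
                "direction": plant.direction,
                "comparison": f"{a_grp} vs {b_grp}",
                "n_sites": n_sites,
                "target_gene": plant.target_gene or "",
            }
        )
    for g in group_names:
        if np.any(level[g] < 0) or np.any(level[g] > 1):
            raise InvalidConfigError("a planted delta pushed a level outside [0, 1]")

    rho = config.dispersion
    conc_bb = (1 - rho) / rho
    for g, n_reps in config.groups:
        lv = level[g]
        a_par = np.clip(lv * conc_bb, 1e-12, None)
        b_par = np.clip((1 - lv) * conc_bb, 1e-12, None)
        for r in range(n_reps):
            cov = rng.poisson(config.mean_coverage, size=n)
            p_rep = rng.beta(a_par, b_par)
            p_rep = np.where(lv <= 0, 0.0, np.where(lv >= 1, 1.0, p_rep))
            meth = rng.binomial(cov, p_rep)
            s = f"{g}_{r + 1}"
            sites[f"m_{s}"] = meth.astype(np.int32)
            sites[f"u_{s}"] = (cov - meth).astype(np.int32)

    truth = TruthTable(
        true_dmrs=pd.DataFrame(
            truth_rows,
            columns=[
                "chrom", "start", "end", "context", "delta", "direction",
                "comparison", "n_sites", "target_gene",
            ],
        ),
        promoter_methylation=_promoter_truth(
            config, genes, prom_levels, group_names
        ),
    )
    return sites, truth


def _promoter_truth(config, genes, prom_levels, group_names):
    rows = []
    plant_by_gene = {}
    for plant in config.planted_dmrs:
        if plant.target_gene:
            plant_by_gene[plant.target_gene] = plant
    for g in genes:
        lvl = {grp: prom_levels[g.gene_id] for grp in group_names}
        plant = plant_by_gene.get(g.gene_id)
        if plant is not None:
            if plant.base_level is not None:
                for grp in group_names:
                    lvl[grp] = plant.base_level
            lvl[plant.comparison[0]] = lvl[plant.comparison[0]] + plant.delta
        rows.append({"gene_id": g.gene_id, **lvl})
    return pd.DataFrame(rows, columns=["gene_id", *group_names])


def simulate_expression(
    config: SimConfig, genes, promoter_methylation: pd.DataFrame, truth: TruthTable | None = None
):
    """Draw the gene x sample negative-binomial count matrix.

    log2 mean per gene and group = gene baseline
    + coupling_strength * promoter methylation + log2fc for planted DEGs
    (applied to the first-named comparison group).  Returns
    (counts DataFrame, gene_lengths Series, TruthTable).
    """
    if config.nb_size <= 0:
        raise InvalidConfigError("negative-binomial size must be positive")
    rng = _stream_rng(config.seed, _SALTS["expression"])
    gene_ids = [g.gene_id for g in genes]
    n_genes = len(gene_ids)
    baseline = rng.normal(config.expr_log2_mean, config.expr_log2_sd, size=n_genes)
    pm = promoter_methylation.set_index("gene_id") if len(promoter_methylation) else None

    group_names = [g for g, _ in config.groups]
    plants = {p.gene_id: p for p in config.planted_degs}
    unknown = set(plants) - set(gene_ids)
    if unknown:
        raise InvalidConfigError(f"planted DEGs for unknown genes: {sorted(unknown)}")

    log2mu = {}
    for grp in group_names:
        mu_g = baseline.copy()
        if pm is not None and config.coupling_strength != 0.0:
            meth = pm[grp].reindex(gene_ids).to_numpy(dtype=float)
            mu_g = mu_g + config.coupling_strength * meth
        log2mu[grp] = mu_g
    for gid, plant in plants.items():
        i = gene_ids.index(gid)
        log2mu[plant.comparison[0]][i] += plant.log2fc

    size = config.nb_size
    data = {}
    for grp, n_reps in config.groups:
        mean = np.exp2(log2mu[grp])
        for r in range(n_reps):
            # library-size wobble, lognormal around 1
            sf = float(np.exp(rng.normal(0.0, 0.08)))
            p_nb = size / (size + mean * sf)
            data[f"{grp}_{r + 1}"] = rng.negative_binomial(size, p_nb)
    counts = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))

    lengths = pd.Series(
        {g.gene_id: abs(g.tts - g.tss) + 1 for g in genes}, name="length"
    ).reindex(gene_ids)

    truth = truth or TruthTable()
    truth.true_degs = pd.DataFrame(
        [
            {
                "gene_id": p.gene_id,
                "log2fc": p.log2fc,
                "direction": p.direction,
                "comparison": f"{p.comparison[0]} vs {p.comparison[1]}",
            }
            for p in config.planted_degs
        ],
        columns=["gene_id", "log2fc", "direction", "comparison"],
    )
    if len(promoter_methylation):
        truth.promoter_methylation = promoter_methylation
    return counts, lengths, truth


def simulate_bsp_clones(
    true_level: float, n_cpg: int, n_clones: int = 10, seed: int = 0
) -> np.ndarray:
    """Bernoulli clone x CpG methylation-call matrix (1 = methylated)."""
    if not 0.0 <= true_level <= 1.0:
        raise InvalidConfigError("true_level must lie in [0, 1]")
    if n_clones < 1 or n_cpg < 1:
        raise InvalidConfigError("need >= 1 clone and >= 1 CpG")
    rng = _stream_rng(seed, _SALTS["bsp"])
    return (rng.random((n_clones, n_cpg)) < true_level).astype(np.int8)


def simulate_term_map(genes, n_terms: int = 30, seed: int = 0, mean_size: int = 25) -> pd.DataFrame:
    """Random term -> gene annotation table (plumbing for enrichment runs)."""
    rng = _stream_rng(seed, _SALTS["terms"])
    gene_ids = [g.gene_id if hasattr(g, "gene_id") else g for g in genes]
    rows = []
    for t in range(n_terms):
        size = max(2, int(rng.poisson(mean_size)))
        size = min(size, len(gene_ids))
        members = rng.choice(gene_ids, size=size, replace=False)
        for gid in sorted(members):
            rows.append({"term_id": f"T{t + 1:04d}", "gene_id": gid,
                         "term_name": f"synthetic term {t + 1}"})
    return pd.DataFrame(rows, columns=["term_id", "gene_id", "term_name"])
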