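"""Methylation-expression integration.

Three views of the joint signal, all restricted to the CG context by
default since essentially all differential methylation sits there:

* metaplots of pooled CG methylation in 40 bp bins across TSS +/- 2000 bp,
  with genes stratified into expression quartiles (highest, medium-high,
  medium-low, lowest);
* a per-gene Spearman correlation between mean TSS-flanking CG methylation
  and log10(FPKM + 1), with a seeded permutation p;
* the DMG intersect DEG table with joint categories (hyper-down, hypo-up,
  hyper-up, hypo-down; genes carrying both hyper and hypo DMRs are set
  aside as both-mixed).

Directions are always relative to the first-named group of the comparison;
mixing orientations silently would corrupt every category, so mismatched
comparison labels are a hard error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OrientationError",
    "STRATA",
    "expression_strata",
    "tss_profile",
    "gene_tss_methylation",
    "profile_correlation",
    "intersect_dmg_deg",
    "classify_integration",
]

STRATA = ("lowest", "medium-low", "medium-high", "highest")


class OrientationError(ValueError):
    """DMG and DEG tables come from differently oriented comparisons."""


def expression_strata(mean_expression: pd.Series) -> pd.Series:
    """Quartile strata of genes by mean expression (FPKM scale).

    Genes with zero expression are excluded (they have no quartile
    position).  The cut is on log10(FPKM + 1) at the 25/50/75 percentiles
    of the ranked genes; ties resolve by stable gene order, so strata sizes
    differ by at most one.
    """
    expr = mean_expression[mean_expression > 0]
    if len(expr) < 4:
        raise ValueError("need >= 4 genes with nonzero expression")
    vals = np.log10(expr.to_numpy(dtype=float) + 1.0)
    if np.ptp(vals) == 0:
        # fully degenerate: no ranking exists, everything ties into one stratum
        import warnings

        warnings.warn("all expression values equal; one stratum only")
        return pd.Series("lowest", index=expr.index, name="stratum")
    order = np.argsort(vals, kind="mergesort")  # stable: ties keep input order
    n = len(vals)
    stratum = np.empty(n, dtype=object)
    # sizes differ by <= 1: quartile boundaries by rounded rank position
    cuts = np.linspace(0, n, 5).round().astype(int)
    for i, name in enumerate(STRATA):
        stratum[order[cuts[i] : cuts[i + 1]]] = name
    return pd.Series(stratum, index=expr.index, name="stratum")


def _signed_offsets(pos: np.ndarray, tss: int, strand: str) -> np.ndarray:
    """Strand-aware offset of genomic positions from the TSS (upstream < 0)."""
    off = pos - tss
    return off if strand == "+" else -off


def gene_tss_methylation(
    sites: pd.DataFrame,
    genes,
    samples,
    window: int = 2000,
    context: str = "CG",
) -> pd.Series:
    """Per-gene count-weighted mean methylation over TSS +/- window.

    Pools the given samples' counts over every ``context`` site in the
    window; genes with no covered site get NaN.
    """
    from .methylome import pooled_counts

    sub = sites[sites["context"].astype(str) == context]
    sub = sub.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    m, u = pooled_counts(sub, samples)
    pos = sub["pos"].to_numpy()
    chrom_arr = sub["chrom"].to_numpy()
    bounds = {}
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        bounds[chrom] = (int(idx[0]), int(idx[-1]) + 1)
    out = {}
    for g in genes:
        if g.chrom not in bounds:
            out[g.gene_id] = np.nan
            continue
        i0, i1 = bounds[g.chrom]
        a = i0 + int(np.searchsorted(pos[i0:i1], g.tss - window, side="left"))
        b = i0 + int(np.searchsorted(pos[i0:i1], g.tss + window, side="right"))
        tot = m[a:b].sum() + u[a:b].sum()
        out[g.gene_id] = (m[a:b].sum() / tot) if tot > 0 else np.nan
    return pd.Series(out, name="tss_methylation")


def tss_profile(
    sites: pd.DataFrame,
    genes,
    strata: pd.Series,
    samples,
    window: int = 2000,
    n_bins: int = 100,
    context: str = "CG",
) -> pd.DataFrame:
    """Pooled methylation metaprofile around the TSS per expression stratum.

    Bins tile [-window, +window) exactly (default 100 x 40 bp); upstream is
    negative regardless of strand.  Per (stratum, bin): pooled level
    sum(m)/sum(m+u) over every CG site of every member gene, the site count,
    and NaN (not zero) where a bin holds no covered site.
    """
    from .methylome import pooled_counts

    sub = sites[sites["context"].astype(str) == context]
    if len(sub) == 0:
        raise ValueError(f"no {context} sites available for the profile")
    sub = sub.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    m, u = pooled_counts(sub, samples)
    pos = sub["pos"].to_numpy()
    chrom_arr = sub["chrom"].to_numpy()
    bounds = {}
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        bounds[chrom] = (int(idx[0]), int(idx[-1]) + 1)

    width = 2 * window / n_bins
    acc_m = {s: np.zeros(n_bins) for s in STRATA}
    acc_u = {s: np.zeros(n_bins) for s in STRATA}
    acc_n = {s: np.zeros(n_bins, dtype=int) for s in STRATA}
    by_gene = {g.gene_id: g for g in genes}
    for gid, stratum in strata.items():
        g = by_gene.get(gid)
        if g is None or g.chrom not in bounds:
            continue
        i0, i1 = bounds[g.chrom]
        a = i0 + int(np.searchsorted(pos[i0:i1], g.tss - window, side="left"))
        b = i0 + int(np.searchsorted(pos[i0:i1], g.tss + window, side="right"))
        if b <= a:
            continue
        off = _signed_offsets(pos[a:b], g.tss, g.strand)
        inside = (off >= -window) & (off < window)
        if not inside.any():
            continue
        bins = ((off[inside] + window) // width).astype(int)
        np.add.at(acc_m[stratum], bins, m[a:b][inside])
        np.add.at(acc_u[stratum], bins, u[a:b][inside])
        np.add.at(acc_n[stratum], bins, 1)

    rows = []
    for s in STRATA:
        tot = acc_m[s] + acc_u[s]
        with np.errstate(invalid="ignore", divide="ignore"):
            lvl = np.where(tot > 0, acc_m[s] / np.maximum(tot, 1), np.nan)
        for b in range(n_bins):
            rows.append(
                {
                    "stratum": s,
                    "bin_start": int(-window + b * width),
                    "bin_end": int(-window + (b + 1) * width),
                    "mean_level": lvl[b],
                    "n_sites": int(acc_n[s][b]),
                }
            )
    return pd.DataFrame(rows)


def profile_correlation(
    tss_methylation: pd.Series,
    expression: pd.Series,
    strata: pd.Series | None = None,
    n_permutations: int = 1999,
    seed: int = 0,
):
    """Spearman rho between TSS-flanking methylation and log10(FPKM + 1).

    p is a two-sided seeded permutation p over >= 1999 expression
    relabelings.  When ``strata`` is given, also reports whether stratum
    mean methylation is strictly anti-ordered with expression.  Constant
    methylation makes the correlation undefined (ValueError).
    """
    joined = pd.concat(
        [tss_methylation.rename("meth"), expression.rename("expr")], axis=1
    ).dropna()
    if len(joined) < 10:
        raise ValueError("need >= 10 genes with methylation and expression")
    meth = joined["meth"].to_numpy()
    expr = np.log10(joined["expr"].to_numpy(dtype=float) + 1.0)
    if np.ptp(meth) == 0:
        raise ValueError("methylation is constant; correlation undefined")
    rho = sps.spearmanr(meth, expr).statistic

    rng = np.random.default_rng(seed)
    r_m = sps.rankdata(meth)
    r_e = sps.rankdata(expr)
    r_m = (r_m - r_m.mean()) / r_m.std()
    r_e = (r_e - r_e.mean()) / r_e.std()
    n = len(r_m)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r = float(r_m @ r_e[perm]) / n
        if abs(r) >= abs(rho) - 1e-12:
            hits += 1
    p_perm = (hits + 1) / (n_permutations + 1)

    monotone = None
    if strata is not None:
        means = [
            joined.loc[joined.index.intersection(strata.index[strata == s]), "meth"].mean()
            for s in STRATA
        ]
        monotone = all(
            np.isfinite(a) and np.isfinite(b) and a > b for a, b in zip(means, means[1:])
        )
    return {"spearman_rho": float(rho), "p_permutation": float(p_perm), "anti_monotone": monotone}


def intersect_dmg_deg(dmgs: pd.DataFrame, degs: pd.DataFrame, comparison: str) -> pd.DataFrame:
    """Genes that are both DMG and DEG in one identically oriented comparison.

    ``degs`` must already be filtered to called DEGs (status up/down).
    Raises OrientationError when either table's recorded comparison label
    disagrees with ``comparison``.
    """
    for tbl, name in ((dmgs, "DMG"), (degs, "DEG")):
        label = tbl.attrs.get("comparison", comparison)
        if label and label != comparison:
            raise OrientationError(
                f"{name} table oriented {label!r}, expected {comparison!r}"
            )
    deg_idx = degs.index if degs.index.name == "gene_id" else pd.Index(degs["gene_id"])
    common = pd.Index(dmgs["gene_id"]).intersection(deg_idx)
    records = []
    dmg_by_gene = dmgs.set_index("gene_id")
    deg_by_gene = degs if degs.index.name == "gene_id" else degs.set_index("gene_id")
    for gid in sorted(common):
        drow = dmg_by_gene.loc[gid]
        erow = deg_by_gene.loc[gid]
        element = (
            "both"
            if (drow["in_promoter"] and drow["in_gene_body"])
            else ("promoter" if drow["in_promoter"] else "gene_body")
        )
        rec = {
            "gene_id": gid,
            "comparison": comparison,
            "meth_direction": drow["direction_summary"],
            "element": element,
            "expr_status": erow["status"],
            "log2fc": float(erow["log2fc"]),
        }
        rec["category"] = classify_integration(rec)
        records.append(rec)
    out = pd.DataFrame(
        records,
        columns=[
            "gene_id", "comparison", "meth_direction", "element",
            "expr_status", "log2fc", "category",
        ],
    )
    out.attrs["comparison"] = comparison
    return out


def classify_integration(record) -> str:
    """Joint category of one DMG-and-DEG gene.

    hyper/hypo methylation x up/down expression, both relative to the same
    first-named group; 'both' methylation maps to 'both-mixed' and is kept
    out of the four clean categories.
    """
    meth = record["meth_direction"]
    expr = record["expr_status"]
    if meth == "both":
        return "both-mixed"
    if meth in ("hyper", "hypo") and expr in ("up", "down"):
        return f"{meth}-{expr}"
    return "unclassified"
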