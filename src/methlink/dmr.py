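"""Differentially methylated region (DMR) calling.

Same-context cytosines are chained into candidate regions (greedy: join the
next site while the inter-site gap stays within ``max_gap`` and the region
span within ``window_span``), replicate counts are pooled per group, and
each region is tested on the pooled 2x2 table with a two-sided Fisher's
exact test.  A region is a DMR when it carries at least ``min_sites``
methylation sites, its pooled level difference exceeds the context
threshold (CG stricter than CHG/CHH, strict inequalities), and the Fisher p
is below alpha.  Direction is hyper when the first-named group of the
comparison is the more methylated one.  No multiplicity correction is used
for the call itself; a Benjamini-Hochberg column is emitted for information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methylome import CONTEXTS, pooled_counts
from .stats import bh_fdr, fisher_exact_two_sided, fisher_exact_two_sided_vec

__all__ = [
    "DmrThresholds",
    "DesignMismatchError",
    "pool_group_counts",
    "build_candidate_regions",
    "fisher_region_test",
    "call_dmrs",
]

fisher_region_test = fisher_exact_two_sided


class DesignMismatchError(ValueError):
    """A sample or group label does not match the design table."""


@dataclass
class DmrThresholds:
    """Call criteria; deltas are strict lower bounds on |level difference|."""

    min_sites: int = 3
    cg_delta: float = 0.3
    hch_delta: float = 0.2  # CHG and CHH
    alpha: float = 0.05
    max_gap: int = 300
    window_span: int = 1000

    def delta_for(self, context: str) -> float:
        return self.cg_delta if context == "CG" else self.hch_delta


def group_samples(design, group: str) -> list[str]:
    """Samples belonging to ``group`` in a sample->group mapping."""
    if isinstance(design, pd.DataFrame):
        design = design.set_index("sample")["group"]
    if isinstance(design, dict):
        design = pd.Series(design)
    samples = [s for s, g in design.items() if g == group]
    if not samples:
        raise DesignMismatchError(f"group {group!r} has no samples in the design")
    return samples


def pool_group_counts(sites: pd.DataFrame, design, group: str):
    """Element-wise pooled (methylated, unmethylated) counts for one group."""
    return pooled_counts(sites, group_samples(design, group))


def build_candidate_regions(
    sites: pd.DataFrame, max_gap: int = 300, window_span: int = 1000
) -> pd.DataFrame:
    """Chain sorted same-context sites into candidate regions.

    ``sites`` must be sorted by (chrom, pos); chaining runs per
    (chrom, context), so a region never mixes contexts.  Returns one row
    per region: chrom, start, end (1-based inclusive), context, n_sites,
    plus row_start / row_end — the global row indices of the first member
    site and one past the last (member rows of other contexts may be
    interleaved between them).
    """
    if len(sites) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "context", "n_sites", "row_start", "row_end"]
        )
    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    if not all(
        np.all(np.diff(pos[chrom == c]) >= 0) for c in pd.unique(chrom)
    ):
        raise ValueError("sites must be sorted by (chrom, pos)")

    regions = []
    ctx_arr = sites["context"].astype(str).to_numpy()
    order = np.arange(len(sites))
    for c in pd.unique(chrom):
        for ctx in CONTEXTS:
            sel = (chrom == c) & (ctx_arr == ctx)
            idx = order[sel]
            if idx.size == 0:
                continue
            p = pos[idx]
            # split where the gap exceeds max_gap, then cap spans greedily
            breaks = np.flatnonzero(np.diff(p) > max_gap) + 1
            run_starts = np.concatenate([[0], breaks])
            run_ends = np.concatenate([breaks, [p.size]])
            for rs, re in zip(run_starts, run_ends):
                s = rs
                while s < re:
                    e = int(np.searchsorted(p, p[s] + window_span, side="right"))
                    e = min(e, re)
                    regions.append(
                        (c, int(p[s]), int(p[e - 1]), ctx, e - s, idx[s], idx[e - 1] + 1)
                    )
                    s = e
    out = pd.DataFrame(
        regions,
        columns=["chrom", "start", "end", "context", "n_sites", "row_start", "row_end"],
    )
    return out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def call_dmrs(
    sites: pd.DataFrame,
    design,
    comparison: tuple[str, str],
    thresholds: DmrThresholds | None = None,
    return_candidates: bool = False,
):
    """Call DMRs for ``comparison = (group_a, group_b)``.

    Pools replicate counts per group per region, computes pooled levels,
    delta = level_a - level_b, a two-sided Fisher p on the pooled table, and
    applies the three criteria.  Regions with zero coverage in either group
    are skipped (reported in the candidate table with NaN statistics).

    Returns the DMR table sorted by (chrom, start); with
    ``return_candidates=True`` also the full candidate-region table with
    statistics and per-filter flags.
    """
    thresholds = thresholds or DmrThresholds()
    group_a, group_b = comparison
    samples_a = group_samples(design, group_a)
    samples_b = group_samples(design, group_b)

    sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    cand = build_candidate_regions(
        sites, max_gap=thresholds.max_gap, window_span=thresholds.window_span
    )
    m_a, u_a = pooled_counts(sites, samples_a)
    m_b, u_b = pooled_counts(sites, samples_b)

    # sites within a region are contiguous rows of the per-(chrom, context)
    # ordering, but not of the global table; sum via per-region slices of
    # cumulative sums over a context-partitioned ordering.
    stats = np.zeros((len(cand), 4), dtype=np.int64)
    if len(cand):
        ctx_arr = sites["context"].astype(str).to_numpy()
        chrom_arr = sites["chrom"].to_numpy()
        pos_arr = sites["pos"].to_numpy()
        counts = np.stack([m_a, u_a, m_b, u_b], axis=1)
        for ctx in CONTEXTS:
            for c in pd.unique(chrom_arr):
                sel = np.flatnonzero((ctx_arr == ctx) & (chrom_arr == c))
                rows = np.flatnonzero(
                    (cand["context"].to_numpy() == ctx) & (cand["chrom"].to_numpy() == c)
                )
                if sel.size == 0 or rows.size == 0:
                    continue
                sub = counts[sel]
                cs = np.zeros((sel.size + 1, 4), dtype=np.int64)
                cs[1:] = np.cumsum(sub, axis=0)
                p = pos_arr[sel]
                lo = np.searchsorted(p, cand["start"].to_numpy()[rows], side="left")
                hi = np.searchsorted(p, cand["end"].to_numpy()[rows], side="right")
                stats[rows] = cs[hi] - cs[lo]

    M_a, U_a, M_b, U_b = stats.T
    cov_a = M_a + U_a
    cov_b = M_b + U_b
    with np.errstate(invalid="ignore", divide="ignore"):
        level_a = np.where(cov_a > 0, M_a / np.maximum(cov_a, 1), np.nan)
        level_b = np.where(cov_b > 0, M_b / np.maximum(cov_b, 1), np.nan)
    delta = level_a - level_b
    testable = (cov_a > 0) & (cov_b > 0)
    p = np.full(len(cand), np.nan)
    if testable.any():
        p[testable] = fisher_exact_two_sided_vec(
            M_a[testable], U_a[testable], M_b[testable], U_b[testable]
        )

    cand = cand.drop(columns=["row_start", "row_end"]).copy()
    cand["m_a"], cand["u_a"], cand["m_b"], cand["u_b"] = M_a, U_a, M_b, U_b
    cand["level_a"], cand["level_b"], cand["delta"] = level_a, level_b, delta
    cand["p_value"] = p
    cand["q_value"] = bh_fdr(p)  # informational only, never a filter
    delta_thr = cand["context"].astype(str).map(
        lambda c: thresholds.delta_for(c)
    ).to_numpy()
    cand["pass_sites"] = cand["n_sites"].to_numpy() >= thresholds.min_sites
    with np.errstate(invalid="ignore"):
        cand["pass_delta"] = np.abs(delta) > delta_thr
        cand["pass_p"] = p < thresholds.alpha
    cand["is_dmr"] = cand["pass_sites"] & cand["pass_delta"] & cand["pass_p"]
    cand["direction"] = np.where(delta > 0, "hyper", "hypo")
    cand.loc[~np.isfinite(delta) | (delta == 0), "direction"] = ""
    cand.attrs["comparison"] = f"{group_a} vs {group_b}"

    dmrs = cand[cand["is_dmr"]].drop(
        columns=["pass_sites", "pass_delta", "pass_p", "is_dmr"]
    )
    dmrs = dmrs.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    dmrs.attrs["comparison"] = f"{group_a} vs {group_b}"
    if return_candidates:
        return dmrs, cand
    return dmrs


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """BED6+ view of a DMR table (0-based half-open, score = -log10 p)."""
    with np.errstate(divide="ignore"):
        score = -np.log10(dmrs["p_value"].to_numpy(dtype=float))
    return pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"] - 1,
            "end": dmrs["end"],
            "name": dmrs["context"].astype(str),
            "score": np.round(score, 4),
            "strand": ".",
            "n_sites": dmrs["n_sites"],
            "level_a": dmrs["level_a"],
            "level_b": dmrs["level_b"],
            "delta": dmrs["delta"],
            "p_value": dmrs["p_value"],
            "direction": dmrs["direction"],
        }
    )
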