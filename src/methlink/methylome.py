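"""Per-cytosine methylation tables and genome-wide summaries.

Bisulfite sequencing reports, per cytosine, how many reads carried a
methylated (unconverted C) versus unmethylated (converted, read as T) call.
Each cytosine is classified by its two downstream bases on its own strand
into the CG, CHG or CHH context (H = A, C or T); in mammals essentially all
methylation sits in the CG context.  This module holds the site-table
conventions used throughout the package and computes the global statistics:
pooled methylation level per context, the share of methylated calls per
context, and the site-level histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NotACytosineError",
    "EdgeUndefinedError",
    "classify_context",
    "genome_cytosine_contexts",
    "site_level",
    "ContextSummary",
    "context_summary",
    "sample_columns",
    "pooled_counts",
]

CONTEXTS = ("CG", "CHG", "CHH")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class NotACytosineError(ValueError):
    """The queried base is not a cytosine on the requested strand."""


class EdgeUndefinedError(ValueError):
    """Fewer than two downstream bases exist; the context is undefined."""


def classify_context(reference: str, pos: int, strand: str) -> str:
    """Classify the cytosine at 1-based ``pos`` on ``strand`` of ``reference``.

    On the minus strand the sequence is read 5'->3' on the reverse
    complement, i.e. the downstream bases are ``pos - 1`` and ``pos - 2`` of
    the forward sequence, complemented.
    """
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    seq = reference.upper()
    if not 1 <= pos <= len(seq):
        raise IndexError(f"position {pos} outside sequence of length {len(seq)}")
    if strand == "+":
        base = seq[pos - 1]
        if base != "C":
            raise NotACytosineError(f"base at +{pos} is {base}, not C")
        if pos + 2 > len(seq):
            raise EdgeUndefinedError(f"position {pos} lacks two downstream bases")
        nxt, nxt2 = seq[pos], seq[pos + 1]
    else:
        base = seq[pos - 1].translate(_COMPLEMENT)
        if base != "C":
            raise NotACytosineError(f"base at -{pos} is {base}, not C")
        if pos - 2 < 1:
            raise EdgeUndefinedError(f"position {pos} lacks two downstream bases")
        nxt = seq[pos - 2].translate(_COMPLEMENT)
        nxt2 = seq[pos - 3].translate(_COMPLEMENT)
    if nxt == "G":
        return "CG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def genome_cytosine_contexts(reference: str) -> pd.DataFrame:
    """Vectorised scan of one chromosome for every context-classifiable cytosine.

    Returns a frame with columns ``pos`` (1-based), ``strand`` and
    ``context``, both strands, excluding edge sites whose context is
    undefined.  Bases other than ACGT never classify as cytosines.
    """
    arr = np.frombuffer(reference.upper().encode("ascii"), dtype="S1")
    L = arr.size
    is_c = arr == b"C"
    is_g = arr == b"G"

    frames = []
    # forward strand: needs bases at i+1, i+2
    fwd = np.flatnonzero(is_c[: max(L - 2, 0)])
    if fwd.size:
        nxt_g = is_g[fwd + 1]
        nxt2_g = is_g[fwd + 2]
        ctx = np.where(nxt_g, "CG", np.where(nxt2_g, "CHG", "CHH"))
        frames.append(
            pd.DataFrame({"pos": fwd + 1, "strand": "+", "context": ctx})
        )
    # reverse strand: a G on the forward strand is a C on the reverse;
    # downstream bases are i-1 and i-2 (forward coords), complemented,
    # so "next is G" on the minus strand means forward base i-1 is C.
    rev = np.flatnonzero(is_g) if L else np.array([], dtype=int)
    rev = rev[rev >= 2]
    if rev.size:
        nxt_g = is_c[rev - 1]
        nxt2_g = is_c[rev - 2]
        ctx = np.where(nxt_g, "CG", np.where(nxt2_g, "CHG", "CHH"))
        frames.append(
            pd.DataFrame({"pos": rev + 1, "strand": "-", "context": ctx})
        )
    if not frames:
        return pd.DataFrame({"pos": pd.Series(dtype=int),
                             "strand": pd.Series(dtype=str),
                             "context": pd.Series(dtype=str)})
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["pos", "strand"], kind="mergesort").reset_index(drop=True)
    out["context"] = pd.Categorical(out["context"], categories=list(CONTEXTS))
    return out


def site_level(count_methylated, count_unmethylated, min_coverage: int = 1):
    """Per-site methylation level m / (m + u); NaN below ``min_coverage``.

    Scalar or array inputs; negative counts raise ``ValueError``.
    """
    m = np.asarray(count_methylated, dtype=float)
    u = np.asarray(count_unmethylated, dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("counts must be non-negative")
    cov = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        lvl = np.where(cov >= max(min_coverage, 1), m / cov, np.nan)
    if lvl.ndim == 0:
        return float(lvl)
    return lvl


def sample_columns(sites: pd.DataFrame) -> list[str]:
    """Sample names present in a site table (paired ``m_<s>`` / ``u_<s>`` columns)."""
    names = [c[2:] for c in sites.columns if c.startswith("m_")]
    missing = [s for s in names if f"u_{s}" not in sites.columns]
    if missing:
        raise ValueError(f"samples missing unmethylated columns: {missing}")
    return names


def pooled_counts(sites: pd.DataFrame, samples) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise sums of methylated / unmethylated counts over ``samples``."""
    samples = list(samples)
    if not samples:
        raise ValueError("no samples to pool")
    m = sum(sites[f"m_{s}"].to_numpy(dtype=np.int64) for s in samples)
    u = sum(sites[f"u_{s}"].to_numpy(dtype=np.int64) for s in samples)
    return m, u


@dataclass
class ContextSummary:
    """Genome-wide methylation summary for one sample or pooled group.

    ``level`` is the count-weighted pooled level sum(m)/sum(m+u) per context
    (``mean_of_sites`` carries the unweighted alternative); ``composition``
    is each context's share of all methylated calls; ``histogram`` counts
    covered sites in ten 10%-wide level bins (last bin right-closed);
    ``methylated_site_fraction`` is the share of covered sites with at least
    one methylated read, reported alongside since a binarisation rule is a
    separate choice from the weighted level.
    """

    level: dict = field(default_factory=dict)
    mean_of_sites: dict = field(default_factory=dict)
    composition: dict = field(default_factory=dict)
    histogram: dict = field(default_factory=dict)
    n_covered: dict = field(default_factory=dict)
    methylated_site_fraction: dict = field(default_factory=dict)
    composition_defined: bool = True

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ctx in CONTEXTS:
            row = {
                "context": ctx,
                "level": self.level.get(ctx, np.nan),
                "mean_of_sites": self.mean_of_sites.get(ctx, np.nan),
                "composition": self.composition.get(ctx, np.nan),
                "n_covered": self.n_covered.get(ctx, 0),
                "methylated_site_fraction": self.methylated_site_fraction.get(ctx, np.nan),
            }
            for b, c in enumerate(self.histogram.get(ctx, [0] * 10)):
                row[f"bin_{10 * b}_{10 * (b + 1)}"] = c
            rows.append(row)
        return pd.DataFrame(rows)


HIST_EDGES = np.linspace(0.0, 1.0, 11)


def context_summary(sites: pd.DataFrame, samples=None, min_coverage: int = 1) -> ContextSummary:
    """Summarise a cytosine table per context over ``samples`` (default: all).

    Raises ``ValueError`` on an empty table.  With zero methylated calls
    overall the composition is undefined and flagged
    (``composition_defined = False``).
    """
    if len(sites) == 0:
        raise ValueError("empty cytosine table")
    if samples is None:
        samples = sample_columns(sites)
    m, u = pooled_counts(sites, samples)
    cov = m + u
    lvl = site_level(m, u, min_coverage=min_coverage)
    ctx_arr = sites["context"].astype(str).to_numpy()

    out = ContextSummary()
    total_meth = int(m.sum())
    out.composition_defined = total_meth > 0
    for ctx in CONTEXTS:
        sel = ctx_arr == ctx
        ms, us, covs = m[sel], u[sel], cov[sel]
        covered = covs >= max(min_coverage, 1)
        n_cov = int(covered.sum())
        out.n_covered[ctx] = n_cov
        denom = int(ms.sum() + us.sum())
        out.level[ctx] = ms.sum() / denom if denom else np.nan
        lv = lvl[sel][covered]
        out.mean_of_sites[ctx] = float(np.mean(lv)) if n_cov else np.nan
        out.composition[ctx] = ms.sum() / total_meth if total_meth else np.nan
        out.methylated_site_fraction[ctx] = (
            float((ms[covered] > 0).mean()) if n_cov else np.nan
        )
        hist, _ = np.histogram(lv, bins=HIST_EDGES)
        out.histogram[ctx] = hist.tolist()
    return out
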