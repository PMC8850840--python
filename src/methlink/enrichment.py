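"""Gene-set over-representation with central and Wallenius noncentral nulls.

The central test asks whether a study set of n genes drawn from a
background of N contains surprisingly many (k) of a term's K genes:
p = P(X >= k), X ~ Hypergeom(N, K, n).  The Wallenius variant biases the
urn: genes carry positive weights (typically a detection-bias weight
derived from gene length), and the term's odds ratio
omega = mean weight inside the term / mean weight outside rescales the
draw.  The Wallenius PMF is computed by the sequential biased-urn
recurrence — after i draws with j successes the next draw succeeds with
probability omega*(K-j) / (omega*(K-j) + (N-K) - (i-j)) — and normalised.
At omega = 1 it reduces exactly to the central hypergeometric.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr

__all__ = [
    "wallenius_pmf",
    "hypergeom_enrich",
    "wallenius_enrich",
    "length_bias_weights",
]


def wallenius_pmf(N: int, K: int, n: int, omega: float, normalize: bool = True) -> np.ndarray:
    """PMF of X = study genes in the term, over x = 0..n.

    Entries outside the feasible range [max(0, n-(N-K)), min(n, K)] are 0.
    The recurrence conserves probability mass step by step; ``normalize``
    only rescales away accumulated floating-point drift (set it False to
    inspect the raw mass).
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K <= N and 0 <= n <= N")
    f = np.zeros(n + 1)
    f[0] = 1.0
    for i in range(n):
        j = np.arange(i + 1)
        w_succ = omega * (K - j)
        w_fail = (N - K) - (i - j)
        w_succ = np.clip(w_succ, 0.0, None)
        w_fail = np.clip(w_fail, 0.0, None)
        tot = w_succ + w_fail
        with np.errstate(invalid="ignore", divide="ignore"):
            ps = np.where(tot > 0, w_succ / np.maximum(tot, 1e-300), 0.0)
        g = np.zeros(n + 1)
        g[j] += f[j] * (1.0 - ps)
        g[j + 1] += f[j] * ps
        f = g
    s = f.sum()
    if s <= 0:
        raise ValueError("degenerate urn: no feasible draw")
    return f / s if normalize else f


def _check_sets(study, background, term_map: pd.DataFrame):
    study = set(study)
    background = set(background)
    stray = study - background
    if stray:
        raise ValueError(f"study genes absent from background: {sorted(stray)[:5]}")
    tm = term_map[term_map["gene_id"].isin(background)]
    return study, background, tm


def hypergeom_enrich(study, background, term_map: pd.DataFrame) -> pd.DataFrame:
    """One-sided central over-representation p per term, with BH q.

    ``term_map`` columns: term_id, gene_id[, term_name]; genes outside the
    background are dropped from the term.
    """
    study, background, tm = _check_sets(study, background, term_map)
    N, n = len(background), len(study)
    rows = []
    for term_id, grp in tm.groupby("term_id", sort=True):
        members = set(grp["gene_id"])
        K = len(members)
        k = len(members & study)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term_id,
                "term_name": grp["term_name"].iloc[0] if "term_name" in grp else "",
                "N": N, "K": K, "n": n, "k": k,
                "weight_ratio": 1.0,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out


def wallenius_enrich(study, background, term_map: pd.DataFrame, weights: pd.Series) -> pd.DataFrame:
    """One-sided Wallenius over-representation p per term, with BH q.

    ``weights`` indexes every background gene with a positive weight; the
    term odds ratio is mean(in-term weights) / mean(out-of-term weights).
    """
    study, background, tm = _check_sets(study, background, term_map)
    weights = weights.reindex(sorted(background))
    if weights.isna().any() or (weights <= 0).any():
        raise ValueError("every background gene needs a positive weight")
    N, n = len(background), len(study)
    rows = []
    for term_id, grp in tm.groupby("term_id", sort=True):
        members = set(grp["gene_id"])
        K = len(members)
        k = len(members & study)
        inside = weights.loc[sorted(members)]
        outside = weights.drop(inside.index)
        omega = float(inside.mean() / outside.mean()) if len(outside) else 1.0
        pmf = wallenius_pmf(N, K, n, omega)
        p = float(pmf[k:].sum())
        rows.append(
            {
                "term_id": term_id,
                "term_name": grp["term_name"].iloc[0] if "term_name" in grp else "",
                "N": N, "K": K, "n": n, "k": k,
                "weight_ratio": omega,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out


def length_bias_weights(
    lengths: pd.Series, is_study: pd.Series, n_bins: int = 30, floor: float = 1e-3
) -> pd.Series:
    """Detection-bias weight per gene from a length-vs-selection fit.

    Genes are binned by length quantiles, the per-bin study fraction is
    isotonic-regressed against the bin median length (longer genes are
    easier to call), and each gene receives its smoothed selection
    probability (floored to stay positive).  This is the probability
    weighting function used to de-bias term enrichment.
    """
    from sklearn.isotonic import IsotonicRegression

    lengths = lengths.astype(float)
    is_study = is_study.reindex(lengths.index).fillna(False).astype(bool)
    ranks = lengths.rank(method="first")
    bins = np.minimum((ranks - 1) // max(len(lengths) // n_bins, 1), n_bins - 1)
    frame = pd.DataFrame({"length": lengths, "study": is_study, "bin": bins})
    per_bin = frame.groupby("bin").agg(
        med_len=("length", "median"), frac=("study", "mean")
    )
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(per_bin["med_len"].to_numpy(), per_bin["frac"].to_numpy())
    w = iso.predict(lengths.to_numpy())
    w = np.clip(w, floor, None)
    return pd.Series(w, index=lengths.index, name="weight")
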