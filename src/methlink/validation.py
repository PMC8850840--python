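"""Wet-lab validation arithmetic: BSP clone scoring and qPCR 2^-ddCt.

Bisulfite sequencing PCR (BSP): a bisulfite-converted amplicon is cloned
and Sanger-sequenced; at each CpG of the untreated reference a clone reads
C when the cytosine was methylated (protected from conversion) and T when
it was not.  Ten clones per sample give a clone x CpG matrix whose mean is
the region methylation level.

qPCR relative quantification: dCt = Ct(target) - Ct(reference gene, GAPDH
by default); ddCt = dCt - mean dCt of the calibrator group; fold change =
2^-ddCt, summarised per group as mean +/- SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

__all__ = [
    "BspCloneMatrix",
    "score_bsp_clones",
    "bsp_region_level",
    "ddct_fold_change",
]


@dataclass
class BspCloneMatrix:
    """Clone x CpG methylation calls: 1 methylated, 0 unmethylated, NaN missing."""

    cpg_positions: list  # 1-based within the region
    calls: pd.DataFrame  # rows = clones, columns = cpg positions

    @property
    def missing_fraction(self) -> float:
        return float(self.calls.isna().to_numpy().mean())


def _find_cpgs(reference: str) -> list[int]:
    ref = reference.upper()
    return [i + 1 for i in range(len(ref) - 1) if ref[i : i + 2] == "CG"]


def _align_map(reference: str, clone: str) -> dict[int, str]:
    """Map 0-based reference positions to clone bases via global alignment.

    End gaps are free so amplicon-length clones with small indels anchor
    cleanly.  Reference positions deleted in the clone are absent.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aligner.end_insertion_score = 0  # free end gaps on either sequence
    aligner.end_deletion_score = 0
    aln = aligner.align(reference.upper(), clone.upper())[0]
    mapping = {}
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            mapping[t0 + k] = clone[q0 + k].upper()
    return mapping


def score_bsp_clones(clones, reference: str, length_tolerance: int = 30) -> BspCloneMatrix:
    """Score clone sequences against the untreated reference region.

    At each reference CpG: clone base C -> methylated, T -> unmethylated,
    anything else (including an alignment gap) -> missing.  Clones whose
    length differs from the reference by more than ``length_tolerance``
    raise a ValueError; equal-length clones are scored by direct indexing,
    others through an end-anchored global alignment.
    """
    cpgs = _find_cpgs(reference)
    if not cpgs:
        raise ValueError("reference region contains no CpG")
    names, rows = [], []
    for idx, clone in enumerate(clones):
        name = getattr(clone, "id", None) or f"clone{idx + 1}"
        seq = str(getattr(clone, "seq", clone))
        if abs(len(seq) - len(reference)) > length_tolerance:
            raise ValueError(
                f"{name}: length {len(seq)} too far from reference {len(reference)}"
            )
        if len(seq) == len(reference):
            base_at = {i: seq[i].upper() for i in range(len(seq))}
        else:
            base_at = _align_map(reference, seq)
        calls = []
        for p in cpgs:
            b = base_at.get(p - 1)
            calls.append(1.0 if b == "C" else (0.0 if b == "T" else np.nan))
        names.append(name)
        rows.append(calls)
    df = pd.DataFrame(rows, index=names, columns=cpgs, dtype=float)
    return BspCloneMatrix(cpg_positions=cpgs, calls=df)


def bsp_region_level(matrix: BspCloneMatrix):
    """(overall level, per-CpG level vector) over non-missing calls."""
    calls = matrix.calls.to_numpy(dtype=float)
    if np.all(np.isnan(calls)):
        raise ValueError("all calls missing; level undefined")
    overall = float(np.nanmean(calls))
    with np.errstate(invalid="ignore"):
        per_cpg = np.nanmean(calls, axis=0)
    return overall, pd.Series(per_cpg, index=matrix.cpg_positions, name="level")


def ddct_fold_change(measurements: pd.DataFrame, calibrator: str):
    """2^-ddCt fold changes per sample, summarised per group and gene.

    ``measurements`` columns: sample, group, gene, ct_target, ct_reference.
    The calibrator-group ddCt reference is the per-gene mean dCt of that
    group, so the calibrator's mean fold change is 1 by construction (up to
    the usual mean-of-2^x vs 2^mean-of-x gap; the geometric mean is exactly
    1).  Returns (per-sample frame with dct/ddct/fold, per-group summary
    with mean and SEM).
    """
    req = {"sample", "group", "gene", "ct_target", "ct_reference"}
    missing = req - set(measurements.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = measurements.copy()
    if df[["ct_target", "ct_reference"]].isna().any().any():
        raise ValueError("incomplete record: missing Ct value")
    if (df[["ct_target", "ct_reference"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    if not (df["group"] == calibrator).any():
        raise ValueError(f"calibrator group {calibrator!r} has no samples")
    df["dct"] = df["ct_target"] - df["ct_reference"]
    cal = (
        df[df["group"] == calibrator]
        .groupby("gene")["dct"]
        .mean()
        .rename("calibrator_dct")
    )
    df = df.join(cal, on="gene")
    if df["calibrator_dct"].isna().any():
        genes = sorted(df.loc[df["calibrator_dct"].isna(), "gene"].unique())
        raise ValueError(f"no calibrator measurements for genes: {genes}")
    df["ddct"] = df["dct"] - df["calibrator_dct"]
    df["fold_change"] = np.exp2(-df["ddct"])
    summary = (
        df.groupby(["gene", "group"])
        .agg(
            mean=("fold_change", "mean"),
            sem=("fold_change", lambda x: x.std(ddof=1) / np.sqrt(len(x))),
            n=("fold_change", "size"),
            fold_from_mean_ddct=("ddct", lambda x: float(np.exp2(-x.mean()))),
        )
        .reset_index()
    )
    return df.drop(columns="calibrator_dct"), summary
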