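"""Expression strata, TSS metaprofiles and joint DMG/DEG categories."""

import numpy as np
import pandas as pd
import pytest

from methlink.annotation import GeneModel
from methlink.integration import (
    STRATA,
    OrientationError,
    classify_integration,
    expression_strata,
    gene_tss_methylation,
    intersect_dmg_deg,
    profile_correlation,
    tss_profile,
)
from tests.conftest import make_site_table


def test_strata_sizes_balanced():
    expr = pd.Series({f"g{i}": float(i + 1) for i in range(8)})
    strata = expression_strata(expr)
    assert strata.value_counts().to_dict() == {s: 2 for s in STRATA}
    assert strata["g0"] == "lowest" and strata["g7"] == "highest"


def test_strata_rank_invariance():
    expr = pd.Series({f"g{i}": float(i + 1) for i in range(12)})
    strata_lin = expression_strata(expr)
    strata_exp = expression_strata(np.expm1(expr / 3.0))  # monotone relabeling
    assert (strata_lin == strata_exp).all()


def test_strata_degenerate_all_equal_warns():
    expr = pd.Series({f"g{i}": 5.0 for i in range(8)})
    with pytest.warns(UserWarning):
        strata = expression_strata(expr)
    assert (strata == strata.iloc[0]).all()


def test_strata_partition_is_exact():
    rng = np.random.default_rng(0)
    expr = pd.Series(rng.random(101) * 50, index=[f"g{i}" for i in range(101)])
    strata = expression_strata(expr)
    assert len(strata) == 101
    sizes = strata.value_counts()
    assert sizes.max() - sizes.min() <= 1


def test_strata_requires_four_genes():
    with pytest.raises(ValueError):
        expression_strata(pd.Series({"g1": 1.0, "g2": 2.0, "g3": 0.0}))


def _uniform_sites(samples, chrom="chr1", lo=1000, hi=30_000, step=37):
    rows = []
    for p in range(lo, hi, step):
        rows.append((chrom, p, "+", "CG", {s: (5, 5) for s in samples}))
    return make_site_table(rows, samples)


def test_tss_profile_constant_field():
    samples = ["s1"]
    sites = _uniform_sites(samples)
    genes = [
        GeneModel("g1", "chr1", "+", 10_000, 14_000, [(10_000, 14_000)]),
        GeneModel("g2", "chr1", "-", 20_000, 16_000, [(16_000, 20_000)]),
        GeneModel("g3", "chr1", "+", 5_000, 8_000, [(5_000, 8_000)]),
        GeneModel("g4", "chr1", "-", 25_000, 22_000, [(22_000, 25_000)]),
    ]
    strata = pd.Series(dict(zip([g.gene_id for g in genes], STRATA)))
    prof = tss_profile(sites, genes, strata, samples)
    filled = prof.dropna(subset=["mean_level"])
    assert np.allclose(filled["mean_level"], 0.5)
    # bins tile the window exactly
    per = prof[prof["stratum"] == "lowest"]
    assert per["bin_start"].iloc[0] == -2000 and per["bin_end"].iloc[-1] == 2000
    assert (per["bin_end"] - per["bin_start"]).nunique() == 1


def test_tss_profile_minus_strand_orientation():
    samples = ["s1"]
    # one methylated site 100 bp downstream of a minus-strand TSS
    rows = [("chr1", 9_900, "+", "CG", {"s1": (10, 0)})]
    sites = make_site_table(rows, samples)
    gene = GeneModel("g1", "chr1", "-", 10_000, 5_000, [(5_000, 10_000)])
    strata = pd.Series({"g1": "highest"})
    prof = tss_profile(sites, gene and [gene], strata, samples)
    hit = prof.dropna(subset=["mean_level"])
    assert len(hit) == 1
    row = hit.iloc[0]
    assert row["stratum"] == "highest"
    assert row["bin_start"] >= 0  # downstream of the TSS maps to positive bins


def test_gene_tss_methylation_weighted_mean():
    samples = ["s1"]
    rows = [
        ("chr1", 9_000, "+", "CG", {"s1": (8, 2)}),
        ("chr1", 11_000, "+", "CG", {"s1": (0, 10)}),
        ("chr1", 50_000, "+", "CG", {"s1": (10, 0)}),  # outside the window
    ]
    sites = make_site_table(rows, samples)
    gene = GeneModel("g1", "chr1", "+", 10_000, 15_000, [(10_000, 15_000)])
    meth = gene_tss_methylation(sites, [gene], samples)
    assert meth["g1"] == pytest.approx(8 / 20)


def test_profile_correlation_perfectly_antiranked():
    meth = pd.Series(np.linspace(0.1, 0.9, 12), index=[f"g{i}" for i in range(12)])
    expr = pd.Series(np.linspace(100, 1, 12), index=[f"g{i}" for i in range(12)])
    out = profile_correlation(meth, expr, n_permutations=499, seed=1)
    assert out["spearman_rho"] == pytest.approx(-1.0)
    assert out["p_permutation"] < 0.05


def test_profile_correlation_constant_methylation_undefined():
    meth = pd.Series(0.5, index=[f"g{i}" for i in range(12)])
    expr = pd.Series(np.arange(12, dtype=float), index=meth.index)
    with pytest.raises(ValueError):
        profile_correlation(meth, expr)


def test_profile_correlation_null_is_calibrated():
    rng = np.random.default_rng(4)
    ps = []
    for _ in range(10):
        meth = pd.Series(rng.random(60), index=[f"g{i}" for i in range(60)])
        expr = pd.Series(rng.random(60) * 100, index=meth.index)
        ps.append(profile_correlation(meth, expr, n_permutations=199, seed=0)["p_permutation"])
    assert min(ps) > 0.001
    assert np.mean(ps) > 0.2


def _dmg_frame(genes, comparison="A vs B", direction="hyper", promoter=True):
    df = pd.DataFrame(
        {
            "gene_id": genes,
            "in_promoter": promoter,
            "in_gene_body": not promoter,
            "direction_summary": direction,
        }
    )
    df.attrs["comparison"] = comparison
    return df


def _deg_frame(genes, comparison="A vs B", status="down"):
    df = pd.DataFrame(
        {"gene_id": genes, "status": status, "log2fc": -2.0 if status == "down" else 2.0}
    ).set_index("gene_id")
    df.attrs["comparison"] = comparison
    return df


def test_intersection_basic_counts():
    out = intersect_dmg_deg(
        _dmg_frame(["a", "b", "c"]), _deg_frame(["b", "c", "d"]), "A vs B"
    )
    assert list(out["gene_id"]) == ["b", "c"]
    empty = intersect_dmg_deg(_dmg_frame(["a"]), _deg_frame(["z"]), "A vs B")
    assert len(empty) == 0


def test_orientation_mismatch_is_hard_error():
    with pytest.raises(OrientationError):
        intersect_dmg_deg(
            _dmg_frame(["a"], comparison="B vs A"), _deg_frame(["a"]), "A vs B"
        )


@pytest.mark.parametrize(
    "meth,expr,expected",
    [
        ("hyper", "down", "hyper-down"),
        ("hypo", "up", "hypo-up"),
        ("hyper", "up", "hyper-up"),
        ("both", "down", "both-mixed"),
    ],
)
def test_classify_integration(meth, expr, expected):
    rec = {"meth_direction": meth, "expr_status": expr}
    assert classify_integration(rec) == expected


def test_integration_categories_in_table():
    out = intersect_dmg_deg(
        _dmg_frame(["a", "b"], direction="hyper"),
        _deg_frame(["a", "b"], status="down"),
        "A vs B",
    )
    assert (out["category"] == "hyper-down").all()
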