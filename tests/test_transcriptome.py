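"""FPKM, DE testing, DEG classification and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from methlink.transcriptome import (
    classify_de,
    cluster_degs,
    compute_fpkm,
    de_analysis,
    de_test,
)


def toy_counts():
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(40)]
    data = {s: rng.poisson(100, size=40) for s in ["a1", "a2", "a3", "b1", "b2", "b3"]}
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))


DESIGN = pd.Series(
    {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"},
    name="group",
).rename_axis("sample")


def test_fpkm_formula():
    counts = pd.DataFrame({"s1": [100]}, index=pd.Index(["g1"], name="gene_id"))
    lengths = pd.Series({"g1": 1000})
    fpkm = compute_fpkm(counts, lengths, library_sizes={"s1": 1_000_000})
    assert fpkm.loc["g1", "s1"] == pytest.approx(100.0)


def test_fpkm_zero_count_and_scaling():
    counts = pd.DataFrame(
        {"s1": [0, 50]}, index=pd.Index(["g1", "g2"], name="gene_id")
    )
    lengths = pd.Series({"g1": 500, "g2": 2000})
    one = compute_fpkm(counts, lengths, library_sizes={"s1": 1e6})
    two = compute_fpkm(counts, lengths, library_sizes={"s1": 2e6})
    assert one.loc["g1", "s1"] == 0.0
    assert np.log10(one.loc["g1", "s1"] + 1) == 0.0
    assert two.loc["g2", "s1"] == pytest.approx(one.loc["g2", "s1"] / 2)


def test_fpkm_rejects_bad_inputs():
    counts = pd.DataFrame({"s1": [1]}, index=pd.Index(["g1"], name="gene_id"))
    with pytest.raises(ValueError):
        compute_fpkm(counts, pd.Series({"g1": 0}))
    with pytest.raises(ValueError):
        compute_fpkm(counts, pd.Series({"g1": 100}), library_sizes={"s1": 0})


def test_identical_groups_null_under_permutation():
    counts = toy_counts()
    for s_a, s_b in zip(["a1", "a2", "a3"], ["b1", "b2", "b3"]):
        counts[s_b] = counts[s_a]
    res = de_test(counts, DESIGN, ("A", "B"), method="permutation")
    assert np.allclose(res["log2fc"], 0.0)
    assert np.allclose(res["p_value"], 1.0)


def test_permutation_support_is_twentieths():
    res = de_test(toy_counts(), DESIGN, ("A", "B"), method="permutation")
    p = res["p_value"].dropna().to_numpy()
    assert np.allclose((p * 20).round(), p * 20)
    assert p.min() >= 1 / 20 - 1e-12


def test_welch_needs_two_replicates():
    design = pd.Series(
        {"a1": "A", "b1": "B", "b2": "B"}, name="group"
    ).rename_axis("sample")
    counts = toy_counts()[["a1", "b1", "b2"]]
    with pytest.raises(ValueError):
        de_test(counts, design, ("A", "B"))


def test_all_zero_gene_excluded():
    counts = toy_counts()
    counts.iloc[0] = 0
    res = de_test(counts, DESIGN, ("A", "B"))
    assert np.isnan(res["p_value"].iloc[0])
    out = de_analysis(counts, DESIGN, ("A", "B"))
    assert out["status"].iloc[0] == "ns"


@pytest.mark.parametrize(
    "log2fc,q,expected",
    [
        (1.5, 0.01, "up"),
        (0.9, 0.001, "ns"),   # fold-change fails (strict > 1)
        (-2.0, 0.049, "down"),
        (1.0, 0.01, "ns"),    # boundary: strict inequality
        (2.0, 0.05, "ns"),    # boundary: strict inequality
        (np.nan, 0.01, "ns"),
    ],
)
def test_classify_de_thresholds(log2fc, q, expected):
    assert classify_de(log2fc, q) == expected


def test_comparison_swap_negates_log2fc():
    counts = toy_counts()
    fwd = de_analysis(counts, DESIGN, ("A", "B"))
    rev = de_analysis(counts, DESIGN, ("B", "A"))
    np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
    np.testing.assert_allclose(fwd["p_value"], rev["p_value"], atol=1e-12)
    assert (fwd["status"] == "up").sum() == (rev["status"] == "down").sum()


def test_cluster_identical_rows_merge_first():
    fpkm = pd.DataFrame(
        {
            "s1": [1.0, 1.0, 50.0],
            "s2": [2.0, 2.0, 10.0],
            "s3": [3.0, 3.0, 5.0],
        },
        index=["g1", "g2", "g3"],
    )
    order, link, flagged = cluster_degs(fpkm)
    assert link[0, 2] == pytest.approx(0.0, abs=1e-12)  # first merge at distance 0
    assert set(link[0, :2].astype(int)) == {0, 1}
    assert flagged == []


def test_cluster_row_order_invariance():
    rng = np.random.default_rng(2)
    fpkm = pd.DataFrame(
        rng.random((6, 4)) * 100, index=[f"g{i}" for i in range(6)],
        columns=["s1", "s2", "s3", "s4"],
    )
    order1, _, _ = cluster_degs(fpkm)
    perm = fpkm.iloc[[3, 1, 5, 0, 4, 2]]
    order2, _, _ = cluster_degs(perm)

    def splits(order):
        return frozenset(frozenset(order[:i]) for i in range(1, len(order)))

    # same topology: compare the merge structure via pairwise cophenetic order
    from scipy.cluster.hierarchy import cophenet
    from scipy.spatial.distance import squareform

    d1 = pd.DataFrame(
        squareform(cophenet(cluster_degs(fpkm)[1])), index=fpkm.index, columns=fpkm.index
    )
    d2 = pd.DataFrame(
        squareform(cophenet(cluster_degs(perm)[1])), index=perm.index, columns=perm.index
    )
    np.testing.assert_allclose(
        d1.loc[fpkm.index, fpkm.index], d2.loc[fpkm.index, fpkm.index], atol=1e-12
    )


def brute_force_average_linkage_3(d):
    """Exhaustive 3-row agglomeration: first merge = closest pair."""
    pairs = list(itertools.combinations(range(3), 2))
    first = min(pairs, key=lambda p: d[p])
    rest = ({0, 1, 2} - set(first)).pop()
    second_height = np.mean([d[tuple(sorted((first[0], rest)))],
                             d[tuple(sorted((first[1], rest)))]])
    return first, d[first], second_height


def test_cluster_three_rows_matches_exhaustive():
    rng = np.random.default_rng(3)
    for _ in range(20):
        fpkm = pd.DataFrame(
            rng.random((3, 5)) * 50, index=["g0", "g1", "g2"],
            columns=[f"s{i}" for i in range(5)],
        )
        _, link, _ = cluster_degs(fpkm)
        X = np.log10(fpkm.to_numpy() + 1)
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        corr = np.corrcoef(Z)
        d = {p: 1 - corr[p] for p in itertools.combinations(range(3), 2)}
        first, h1, h2 = brute_force_average_linkage_3(d)
        assert set(link[0, :2].astype(int)) == set(first)
        assert link[0, 2] == pytest.approx(h1, abs=1e-10)
        assert link[1, 2] == pytest.approx(h2, abs=1e-10)


def test_constant_row_flagged():
    fpkm = pd.DataFrame(
        {"s1": [5.0, 1.0], "s2": [5.0, 2.0], "s3": [5.0, 3.0]},
        index=["flat", "rise"],
    )
    _, _, flagged = cluster_degs(fpkm)
    assert flagged == ["flat"]
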