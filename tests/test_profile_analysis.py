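import itertools
import math

import numpy as np
import pandas as pd
import pytest

from spiscreen.io_cli.layout import InteractionNetwork
from spiscreen.profile_analysis import (
    MAX_DISTANCE,
    abundance_binning,
    cluster_profiles,
    fisher_enrichment,
    headline_proportions,
    interaction_density_rank,
    screen_correlation,
    spi_frequency,
    summary_stats,
    term_enrichment,
)


# ---------------------------------------------------------------------------
# screen correlation
# ---------------------------------------------------------------------------

def test_duplicated_screen_correlates_perfectly(rng):
    a = rng.normal(size=50)
    m = pd.DataFrame({"s1": a, "s2": a.copy(), "s3": rng.normal(size=50)})
    corr = screen_correlation(m)
    assert corr.loc["s1", "s2"] == pytest.approx(1.0)
    assert np.all(np.diag(corr) == 1.0)


def test_negated_screen_correlates_minus_one(rng):
    a = rng.normal(size=30)
    corr = screen_correlation(pd.DataFrame({"s1": a, "s2": -a}))
    assert corr.loc["s1", "s2"] == pytest.approx(-1.0)


def test_spearman_invariant_to_monotone_transform(rng):
    a = rng.normal(size=40)
    b = rng.normal(size=40)
    c1 = screen_correlation(pd.DataFrame({"s1": a, "s2": b}))
    c2 = screen_correlation(pd.DataFrame({"s1": np.exp(a), "s2": b ** 3}))
    assert c1.loc["s1", "s2"] == pytest.approx(c2.loc["s1", "s2"])


def test_shared_spis_raise_correlation(rng):
    within, between = [], []
    for seed in range(20):
        r = np.random.default_rng(seed)
        n = 200
        shared = r.normal(0, 1, n) + 3.0 * (r.random(n) < 0.05)
        s1 = shared + r.normal(0, 0.5, n)
        s2 = shared + r.normal(0, 0.5, n)
        s3 = r.normal(0, 1, n)
        corr = screen_correlation(pd.DataFrame({"s1": s1, "s2": s2, "s3": s3}))
        within.append(corr.loc["s1", "s2"])
        between.append(corr.loc["s1", "s3"])
    assert np.mean(within) > np.mean(between) + 0.3


# ---------------------------------------------------------------------------
# clustering (with brute-force oracle)
# ---------------------------------------------------------------------------

def _oracle_centroid_linkage(data):
    """Independent brute-force centroid linkage under 1 - Pearson."""
    def dist(u, v):
        ok = np.isfinite(u) & np.isfinite(v)
        if ok.sum() < 2 or u[ok].std() == 0 or v[ok].std() == 0:
            return MAX_DISTANCE
        return 1.0 - float(np.corrcoef(u[ok], v[ok])[0, 1])

    clusters = {i: [i] for i in range(len(data))}
    merges = []
    next_id = len(data)
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            ci = np.nanmean(data[clusters[i]], axis=0)
            cj = np.nanmean(data[clusters[j]], axis=0)
            d = dist(ci, cj)
            if best is None or (d, i, j) < best[:3]:
                best = (d, i, j)
        d, i, j = best
        merges.append((frozenset(clusters[i] + clusters[j]), d))
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return merges


@pytest.mark.parametrize("n_rows", [3, 4, 5, 6])
def test_cluster_matches_brute_force(n_rows):
    for seed in range(25):
        rng = np.random.default_rng(1000 * n_rows + seed)
        data = rng.normal(size=(n_rows, 5))
        tree = cluster_profiles(pd.DataFrame(data))
        oracle = _oracle_centroid_linkage(data)
        n = n_rows
        for step, (members, height) in enumerate(oracle):
            a, b, h, cnt = tree.linkage[step]

            def leafset(idx):
                idx = int(idx)
                if idx < n:
                    return frozenset([idx])
                aa, bb = tree.linkage[idx - n, 0], tree.linkage[idx - n, 1]
                return leafset(aa) | leafset(bb)

            assert leafset(a) | leafset(b) == members
            assert h == pytest.approx(height, abs=1e-12)


def test_identical_rows_merge_first_at_zero():
    data = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, -1.0, 0.5]])
    # rows 0 and 1 are perfectly correlated -> distance 0
    tree = cluster_profiles(pd.DataFrame(data))
    assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert {int(tree.linkage[0, 0]), int(tree.linkage[0, 1])} == {0, 1}


def test_two_planted_groups_split_at_top():
    for seed in range(10):
        rng = np.random.default_rng(seed)
        base1, base2 = rng.normal(size=10), rng.normal(size=10)
        rows = [base1 + rng.normal(0, 0.3, 10) for _ in range(4)] + \
               [base2 + rng.normal(0, 0.3, 10) for _ in range(4)]
        tree = cluster_profiles(pd.DataFrame(rows))
        order = tree.leaf_order()
        first_half = {int(x) for x in order[:4]}
        assert first_half in ({0, 1, 2, 3}, {4, 5, 6, 7})


def test_cluster_drops_sparse_rows():
    data = pd.DataFrame([[1.0, np.nan, np.nan],
                         [1.0, 2.0, 3.0],
                         [3.0, 1.0, 2.0],
                         [0.0, 5.0, 1.0]])
    tree = cluster_profiles(data)
    assert tree.dropped == ["0"]
    assert tree.n_leaves == 3


def test_constant_row_flagged_and_maximally_distant():
    data = pd.DataFrame([[1.0, 1.0, 1.0, 1.0],
                         [1.0, 2.0, 3.0, 4.0],
                         [4.0, 3.0, 2.0, 1.0]])
    tree = cluster_profiles(data)
    assert "0" in tree.flagged_constant
    # the constant row merges last, at the maximal distance
    assert tree.linkage[-1, 2] == pytest.approx(MAX_DISTANCE)


def test_cluster_invariant_to_row_permutation(rng):
    data = rng.normal(size=(8, 6))
    df = pd.DataFrame(data, index=[f"r{i}" for i in range(8)])
    perm = rng.permutation(8)
    tree1 = cluster_profiles(df)
    tree2 = cluster_profiles(df.iloc[perm])
    # same tree: identical merge heights and identical leaf-label order
    np.testing.assert_allclose(np.sort(tree1.linkage[:, 2]),
                               np.sort(tree2.linkage[:, 2]), atol=1e-12)
    def partition(tree):
        n = tree.n_leaves
        sets = []
        for k in range(n - 1):
            def leafset(idx):
                idx = int(idx)
                if idx < n:
                    return frozenset([tree.leaves[idx]])
                a, b = tree.linkage[idx - n, :2]
                return leafset(a) | leafset(b)
            sets.append(leafset(n + k))
        return set(sets)
    assert partition(tree1) == partition(tree2)


# ---------------------------------------------------------------------------
# SPI frequency + abundance binning
# ---------------------------------------------------------------------------

def _calls(counts):
    rows = []
    for q, k in counts.items():
        for t in range(23):
            rows.append({"query": q, "target": f"T{t:02d}", "confirmed": t < k})
    return pd.DataFrame(rows)


def test_frequency_boundary_at_ten():
    out = spi_frequency(_calls({"q10": 10, "q9": 9})).set_index("query")
    assert bool(out.loc["q10", "frequent"]) is True
    assert bool(out.loc["q9", "frequent"]) is False


def test_frequency_histogram_matches_truth(rng):
    truth = {f"q{i}": int(k) for i, k in enumerate(rng.integers(0, 23, size=60))}
    out = spi_frequency(_calls(truth)).set_index("query")["n_spi_targets"]
    assert {q: int(v) for q, v in out.items()} == truth


def test_abundance_bins_of_421():
    ann = pd.DataFrame({
        "protein": [f"p{i}" for i in range(3368)],
        "abundance": np.arange(3368, dtype=float) + 1.0,
    })
    out = abundance_binning(ann, spi_queries=set(), n_bins=8)
    assert out["n_proteins"].tolist() == [421] * 8


def test_abundance_remainder_to_lowest_bins():
    ann = pd.DataFrame({"protein": [f"p{i}" for i in range(10)],
                        "abundance": np.arange(10, dtype=float)})
    out = abundance_binning(ann, spi_queries=set(), n_bins=4)
    assert out["n_proteins"].tolist() == [3, 3, 2, 2]


def test_uniform_spis_give_flat_bins():
    rng = np.random.default_rng(0)
    props = []
    for seed in range(200):
        r = np.random.default_rng(seed)
        ann = pd.DataFrame({"protein": [f"p{i}" for i in range(800)],
                            "abundance": r.lognormal(5, 1.5, 800)})
        spis = set(ann["protein"][r.random(800) < 0.1])
        out = abundance_binning(ann, spis, n_bins=8)
        props.append(out["spi_fraction"].to_numpy())
    mean_props = np.mean(props, axis=0)
    np.testing.assert_allclose(mean_props, 0.1, atol=0.01)


def test_concentrated_spis_blow_up_one_bin():
    ann = pd.DataFrame({"protein": [f"p{i}" for i in range(800)],
                        "abundance": np.arange(800, dtype=float)})
    spis = set(ann["protein"][:100])  # all in the lowest bin
    out = abundance_binning(ann, spis, n_bins=8)
    assert out.loc[0, "spi_fraction"] == pytest.approx(1.0)
    assert out.loc[0, "spi_fraction"] == pytest.approx(
        8 * out["spi_fraction"].mean())


# ---------------------------------------------------------------------------
# Fisher + term enrichment
# ---------------------------------------------------------------------------

def _fisher_oracle(a, b, c, d):
    """One-sided p by exact hypergeometric tail summation (integer comb)."""
    n1, K, N = a + b, a + c, a + b + c + d
    total = math.comb(N, n1)
    tail = sum(math.comb(K, x) * math.comb(N - K, n1 - x)
               for x in range(a, min(n1, K) + 1))
    return tail / total


def test_fisher_symmetric_table_oracle():
    odds, p, flagged = fisher_enrichment((5, 5), (5, 5))
    assert p == pytest.approx(_fisher_oracle(5, 5, 5, 5), rel=1e-12)
    assert odds == pytest.approx(1.0)
    assert not flagged


def test_fisher_diagonal_table_closed_form():
    _, p, flagged = fisher_enrichment((10, 0), (0, 10))
    assert p == pytest.approx(1 / math.comb(20, 10), rel=1e-12)
    assert p == pytest.approx(5.4e-6, rel=0.01)
    assert flagged  # zero cells -> Haldane-corrected odds ratio


def test_fisher_empty_in_group_p_one():
    _, p, _ = fisher_enrichment((0, 10), (5, 5))
    assert p == pytest.approx(1.0)


def test_fisher_zero_margin_rejected():
    with pytest.raises(ValueError, match="margins"):
        fisher_enrichment((0, 0), (5, 5))


def test_fisher_matches_enumeration_sampled():
    rng = np.random.default_rng(4)
    for _ in range(300):
        a, b, c, d = rng.integers(0, 15, size=4)
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        _, p, _ = fisher_enrichment((int(a), int(b)), (int(c), int(d)))
        assert p == pytest.approx(_fisher_oracle(int(a), int(b), int(c), int(d)),
                                  rel=1e-9)


def test_term_enrichment_self_set_top_ranked():
    universe = {f"g{i}" for i in range(100)}
    target = {f"g{i}" for i in range(10)}
    sets = {"hit": target, "miss": {f"g{i}" for i in range(50, 60)}}
    out = term_enrichment(target, sets, universe)
    assert out.iloc[0]["term"] == "hit"
    expected = 1 / math.comb(100, 10) * 1  # only one way to draw the full set
    assert out.iloc[0]["p"] == pytest.approx(expected, rel=1e-9)


def test_term_enrichment_disjoint_p_one():
    universe = {f"g{i}" for i in range(40)}
    out = term_enrichment({"g0", "g1"}, {"t": {"g30", "g31"}}, universe)
    assert out["p"].iloc[0] == 1.0


def test_term_enrichment_null_p_uniform():
    # random gene sets: pooled p-values roughly uniform
    universe = [f"g{i}" for i in range(200)]
    sets = {f"t{j}": set(np.random.default_rng(j).choice(universe, 30, replace=False))
            for j in range(5)}
    ps = []
    for seed in range(200):
        rng = np.random.default_rng(10_000 + seed)
        genes = set(rng.choice(universe, 20, replace=False))
        out = term_enrichment(genes, sets, set(universe))
        ps.extend(out["p"])
    # hypergeometric p under the null is super-uniform (discrete, conservative)
    ps = np.asarray(ps)
    assert (ps < 0.05).mean() <= 0.07
    assert np.median(ps) > 0.25


def test_term_enrichment_requires_subset():
    with pytest.raises(ValueError, match="subset"):
        term_enrichment({"x"}, {}, {"a", "b"})


# ---------------------------------------------------------------------------
# interaction density
# ---------------------------------------------------------------------------

def test_density_on_complete_graph_is_one(rng):
    proteins = [f"p{i}" for i in range(20)]
    net = InteractionNetwork.from_pairs(itertools.combinations(proteins, 2))
    res = interaction_density_rank(proteins, net, n_perm=100, seed=0)
    np.testing.assert_allclose(res.curve["density"], 1.0)


def test_density_edgeless_network():
    proteins = [f"p{i}" for i in range(30)]
    net = InteractionNetwork.from_pairs([])
    res = interaction_density_rank(proteins, net, n_perm=100, seed=0)
    assert res.k_star is None
    assert res.p_value == 1.0
    np.testing.assert_allclose(res.curve["density"], 0.0)


def test_density_planted_top_block():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        proteins = [f"p{i:04d}" for i in range(1000)]
        top = proteins[:50]
        pairs = [(a, b) for a, b in itertools.combinations(top, 2)
                 if rng.random() < 0.4]
        net = InteractionNetwork.from_pairs(pairs)
        res = interaction_density_rank(proteins, net, n_perm=199, seed=seed)
        assert 40 <= res.k_star <= 80
        assert res.p_value <= 1 / 200


def test_density_null_p_not_extreme():
    rng = np.random.default_rng(9)
    proteins = [f"p{i:04d}" for i in range(300)]
    pairs = [(a, b) for a, b in itertools.combinations(proteins, 2)
             if rng.random() < 0.01]
    net = InteractionNetwork.from_pairs(pairs)
    ps = []
    for seed in range(20):
        order = list(np.random.default_rng(seed).permutation(proteins))
        ps.append(interaction_density_rank(order, net, n_perm=100, seed=seed).p_value)
    # p should not concentrate at the minimum under the null
    assert np.mean(np.asarray(ps) <= 1 / 101) < 0.3
    assert np.mean(ps) > 0.1


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def test_headline_proportions_arithmetic():
    counts = {
        "benign_combinations": 129_098, "total_combinations": 131_882,
        "colocalized": 225, "scorable_cross_compartment": 314,
        "same_compartment": 210, "scored_combinations": 524,
        "total_spis": 2784, "spi_queries": 727,
        "spi_queries_with_human_homolog": 549,
        "diploid_reproduced": 6, "nonfrequent_group": 40,
    }
    out = headline_proportions(counts)
    assert out["benign_pct"]["value"] == 98
    assert out["colocalized_pct"]["value"] == 72
    assert out["same_compartment_pct"]["value"] == 40
    assert out["mean_spis_per_query"]["value"] == 3.8
    assert out["human_homolog_pct"]["value"] == 76
    assert out["diploid_reproduced_pct"]["value"] == 15


def test_summary_undefined_ratios_are_none_not_zero():
    out = headline_proportions({"total_spis": 0, "spi_queries": 0})
    assert out["mean_spis_per_query"]["value"] is None
    assert out["benign_pct"]["value"] is None


def test_summary_stats_from_calls():
    calls = pd.DataFrame({
        "query": ["a", "a", "b"], "target": ["T00", "T01", "T00"],
        "confirmed": [True, True, True]})
    ann = pd.DataFrame({
        "protein": ["a", "b"], "compartment": ["nuc", "cyt"],
        "abundance": [1.0, 2.0], "essential": [False, True],
        "validated_gfp": [True, True], "human_homolog": [True, False]})
    out = summary_stats(spi_calls=calls, annotations=ann)
    assert out["mean_spis_per_query"]["value"] == 1.5
    assert out["human_homolog_pct"]["value"] == 50
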