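"""Filters against brute-force re-application, π against the O(n^2)
pairwise oracle, haplotype grouping, dominance, median-joining networks
and genotype PCA."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import make_matrix
from zfamkit.io import MISSING
from zfamkit.popgen import (
    build_mj_network,
    call_haplotypes,
    diversity_reduction,
    dominant_haplotype,
    filter_samples,
    filter_sites,
    genotype_pca,
    hamming,
    nucleotide_diversity,
    site_pi,
)


def pairwise_pi(col):
    """Mean pairwise difference at one site over all non-missing pairs."""
    obs = [c for c in col if c != MISSING]
    pairs = list(itertools.combinations(obs, 2))
    if not pairs:
        return float("nan")
    return sum(a != b for a, b in pairs) / len(pairs)


class TestFilters:
    def test_low_frequency_site_removed(self):
        m = make_matrix(np.array([[1] + [0] * 49]).T.reshape(50, 1))
        out, log = filter_sites(m)
        assert out.n_sites == 0
        assert log["reason"].tolist() == ["allele_frequency"]

    def test_missing_rate_site_removed(self):
        calls = np.zeros((20, 1), dtype=np.int8)
        calls[:10, 0] = 1
        calls[:3, 0] = MISSING  # 15% missing
        out, log = filter_sites(make_matrix(calls))
        assert out.n_sites == 0
        assert log["reason"].tolist() == ["missing_rate"]

    def test_thresholds_are_strict(self):
        # exactly 10% missing fails "< 0.1"; frequency exactly 0.05 fails
        calls = np.zeros((20, 1), dtype=np.int8)
        calls[:10, 0] = 1
        calls[:2, 0] = MISSING
        assert filter_sites(make_matrix(calls))[0].n_sites == 0
        calls2 = np.zeros((20, 1), dtype=np.int8)
        calls2[0, 0] = 1  # freq 0.05 exactly
        assert filter_sites(make_matrix(calls2))[0].n_sites == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_refilter(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.choice(
            [0, 1, MISSING], p=[0.5, 0.42, 0.08], size=(40, 200)
        ).astype(np.int8)
        m = make_matrix(calls, gene_ids=[f"g{j % 20}" for j in range(200)])
        out, _ = filter_sites(m)
        expected = []
        for j in range(200):
            col = calls[:, j]
            missing = (col == MISSING).mean()
            obs = col[col != MISSING]
            freq = obs.mean() if obs.size else 0.0
            if missing < 0.1 and 0.05 < freq < 0.95:
                expected.append(j)
        assert out.sites["position"].tolist() == [
            (j + 1) * 100 for j in expected
        ]

    def test_filter_idempotent(self, rng):
        calls = rng.choice([0, 1, MISSING], p=[0.5, 0.42, 0.08], size=(30, 100))
        m = make_matrix(calls.astype(np.int8))
        once, _ = filter_sites(m)
        twice, _ = filter_sites(once)
        assert once.sites.equals(twice.sites)
        assert np.array_equal(once.calls, twice.calls)

    def test_sample_filter_thresholds(self):
        calls = np.zeros((3, 10), dtype=np.int8)
        calls[1, :5] = MISSING  # 50% missing -> drop
        out = filter_samples(make_matrix(calls))
        assert out.samples == ["S1", "S3"]

    @pytest.mark.parametrize("seed", range(5))
    def test_sample_filter_matches_direct_count(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.choice([0, 1, MISSING], p=[0.5, 0.35, 0.15], size=(25, 40))
        m = make_matrix(calls.astype(np.int8))
        out = filter_samples(m, 0.1)
        kept = [
            f"S{i+1}" for i in range(25) if (calls[i] == MISSING).mean() <= 0.1
        ]
        assert out.samples == kept


class TestDiversity:
    def test_two_samples_one_difference(self):
        assert site_pi(np.array([0, 1], dtype=np.int8)) == pytest.approx(1.0)

    def test_monomorphic_site(self):
        assert site_pi(np.array([1, 1, 1], dtype=np.int8)) == 0.0

    @pytest.mark.parametrize("n", range(2, 13))
    def test_pairwise_oracle_all_small_instances(self, n):
        rng = np.random.default_rng(n)
        for _ in range(30):
            col = rng.choice([0, 1, MISSING], p=[0.4, 0.4, 0.2], size=n).astype(
                np.int8
            )
            expected = pairwise_pi(col)
            got = site_pi(col)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)

    def test_per_gene_and_overall_means(self, small_matrix):
        res = nucleotide_diversity(
            small_matrix, small_matrix.samples, "all"
        )
        cols = [pairwise_pi(small_matrix.calls[:, j]) for j in range(4)]
        assert res.pi_per_gene["g1"] == pytest.approx(np.mean(cols[:2]))
        assert res.pi_overall == pytest.approx(np.nanmean(cols))
        assert res.n_sites_used == 4

    def test_population_too_small_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            nucleotide_diversity(small_matrix, ["S1"])

    def test_reduction_statistic(self):
        assert diversity_reduction(0.1050, 0.0739) == pytest.approx(29.6190, abs=1e-3)
        assert diversity_reduction(0.5, 0.5) == 0.0
        assert diversity_reduction(0.3, 0.0) == 100.0
        assert np.isnan(diversity_reduction(0.0, 0.0))


class TestHaplotypes:
    def test_grouping_counts(self):
        m = make_matrix([[0, 0], [0, 0], [0, 1]], samples=["w1", "w2", "l1"])
        table = call_haplotypes(
            m, "g1", {"w1": "wild", "w2": "wild", "l1": "landrace"}
        )
        assert table.haplotypes == [("00", 2, 0), ("01", 0, 1)]
        assert table.n_dropped_samples == 0

    def test_missing_call_drops_sample_everywhere(self):
        m = make_matrix([[0, 0], [0, MISSING]], samples=["w1", "w2"])
        table = call_haplotypes(m, "g1", {"w1": "wild", "w2": "wild"})
        assert table.n_dropped_samples == 1
        assert table.total_retained == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_partition_equals_string_grouping(self, seed):
        rng = np.random.default_rng(seed)
        calls = rng.choice([0, 1, MISSING], p=[0.45, 0.45, 0.1], size=(30, 6))
        pops = {f"S{i+1}": ("wild" if i < 15 else "landrace") for i in range(30)}
        m = make_matrix(calls.astype(np.int8))
        table = call_haplotypes(m, "g1", pops)
        # conservation
        assert table.total_retained + table.n_dropped_samples == 30
        # brute-force grouping
        expected = {}
        for i in range(30):
            row = calls[i]
            if (row == MISSING).any():
                continue
            h = "".join(map(str, row))
            expected.setdefault(h, [0, 0])[0 if i < 15 else 1] += 1
        assert {h: (w, l) for h, w, l in table.haplotypes} == {
            h: tuple(v) for h, v in expected.items()
        }
        # ordering: total desc then lexicographic
        keys = [(-(w + l), h) for h, w, l in table.haplotypes]
        assert keys == sorted(keys)

    def test_dominant_strictly_more_than_half(self):
        m = make_matrix(
            [[0], [0], [0], [1], [0], [1]],
            samples=[f"w{i}" for i in range(4)] + ["l1", "l2"],
        )
        pops = {f"w{i}": "wild" for i in range(4)}
        pops.update({"l1": "landrace", "l2": "landrace"})
        table = call_haplotypes(m, "g1", pops)
        assert dominant_haplotype(table, "wild") == "0"  # 3/4 > 1/2
        assert dominant_haplotype(table, "landrace") is None  # exactly 1/2

    def test_populations_may_have_distinct_dominants(self):
        # wild fixed on one haplotype, landrace on another
        m = make_matrix(
            [[0, 0]] * 3 + [[1, 1]] * 3,
            samples=["w1", "w2", "w3", "l1", "l2", "l3"],
        )
        pops = {s: ("wild" if s.startswith("w") else "landrace")
                for s in m.samples}
        table = call_haplotypes(m, "g1", pops)
        assert dominant_haplotype(table, "wild") == "00"
        assert dominant_haplotype(table, "landrace") == "11"

    def test_dominance_unique(self, rng):
        for _ in range(20):
            calls = rng.choice([0, 1], size=(12, 4)).astype(np.int8)
            pops = {f"S{i+1}": "wild" for i in range(12)}
            table = call_haplotypes(make_matrix(calls), "g1", pops)
            total = table.population_total("wild")
            n_dominant = sum(1 for _, w, _ in table.haplotypes if w > total / 2)
            assert n_dominant <= 1

    def test_gene_without_sites_warns(self, small_matrix):
        with pytest.warns(UserWarning):
            table = call_haplotypes(small_matrix, "absent", {})
        assert table.haplotypes == []


def brute_force_best_single_insertion(nodes):
    """Minimum spanning length achievable by adding at most one extra
    binary vector, by exhaustive search (instances with <= 4 sites)."""
    from zfamkit.popgen import _mst_length

    L = len(nodes[0])
    best = _mst_length(nodes)
    for bits in itertools.product("01", repeat=L):
        cand = "".join(bits)
        best = min(best, _mst_length(list(nodes) + [cand]))
    return best


class TestMjNetwork:
    def test_two_haplotypes_single_edge(self):
        net = build_mj_network(["00", "01"])
        assert list(net.graph.edges(data="weight")) == [("00", "01", 1)]
        assert net.medians == []

    def test_triangle_gains_median(self):
        net = build_mj_network(["000", "011", "101"])
        from zfamkit.popgen import _mst_length

        assert net.total_length <= _mst_length(["000", "011", "101"])
        # any added median must be a coordinate-wise majority of a triplet
        observed = ["000", "011", "101"]
        for m in net.medians:
            majorities = {
                "".join(
                    x if (x == y or x == z) else (y if y == z else x)
                    for x, y, z in zip(u, v, w)
                )
                for u, v, w in itertools.combinations(observed + net.medians, 3)
            }
            assert m in majorities
        # brute force: no single insertion beats the achieved length
        assert net.total_length == brute_force_best_single_insertion(observed)

    def test_star_needs_no_median(self):
        net = build_mj_network(["000", "100", "010", "001"])
        assert net.medians == []
        assert net.total_length == 3
        assert net.total_length == brute_force_best_single_insertion(
            ["000", "100", "010", "001"]
        )

    @pytest.mark.parametrize("seed", range(12))
    def test_random_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(2, 5))
        n = int(rng.integers(2, 6))
        haps = sorted(
            {"".join(map(str, rng.integers(0, 2, size=L))) for _ in range(n)}
        )
        net = build_mj_network(haps)
        g = net.graph
        assert nx.is_connected(g)
        assert set(haps) <= set(g.nodes)
        for u, v, w in g.edges(data="weight"):
            assert w == hamming(u, v) >= 1
        from zfamkit.popgen import _mst_length

        assert net.total_length <= _mst_length(haps)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_mj_network(["00", "000"])


class TestPca:
    def test_duplicated_samples_identical_coordinates(self):
        m = make_matrix([[0, 1, 0], [0, 1, 0], [1, 0, 1], [1, 0, 0]])
        res = genotype_pca(m, 2)
        assert np.allclose(res.coordinates[0], res.coordinates[1])

    def test_explained_variance_against_sklearn(self, rng):
        from sklearn.decomposition import PCA

        calls = rng.choice([0, 1], size=(20, 40)).astype(np.int8)
        m = make_matrix(calls)
        res = genotype_pca(m, 5)
        # reproduce scaling independently, then compare spectra
        X = calls.astype(float)
        p = X.mean(axis=0)
        keep = (p > 0) & (p < 1)
        Z = (X[:, keep] - p[keep]) / np.sqrt(p[keep] * (1 - p[keep]))
        sk = PCA(n_components=5).fit(Z)
        assert np.allclose(
            res.explained_variance / 100, sk.explained_variance_ratio_, atol=1e-8
        )
        assert res.explained_variance.tolist() == sorted(
            res.explained_variance, reverse=True
        )

    def test_permuting_samples_permutes_coordinates(self, rng):
        calls = rng.choice([0, 1], size=(15, 30)).astype(np.int8)
        perm = rng.permutation(15)
        r1 = genotype_pca(make_matrix(calls), 3)
        r2 = genotype_pca(make_matrix(calls[perm]), 3)
        assert np.allclose(r1.coordinates[perm], r2.coordinates, atol=1e-8)

    def test_disjoint_founder_pools_separate_on_pc1(self):
        from zfamkit.synthetic_data import BottleneckSpec, make_genotypes

        m, pops = make_genotypes(BottleneckSpec(seed=11, missing_rate=0.0))
        res = genotype_pca(m, 2)
        pc1 = res.coordinates[:, 0]
        wild = np.array([pops[s] == "wild" for s in res.samples])
        d = abs(pc1[wild].mean() - pc1[~wild].mean())
        spread = pc1[wild].std() + pc1[~wild].std()
        assert d > 0  # populations displaced along PC1
        assert d > 0.5 * spread

    def test_insufficient_sites_warns(self):
        m = make_matrix([[0, 0], [1, 1], [0, 1]])
        with pytest.warns(UserWarning):
            res = genotype_pca(m, 5)
        assert res.coordinates.shape[1] < 5
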