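import itertools
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pytest

from lfsn.enrichment import CandidateModule, EnrichmentResult
from lfsn.io_formats import GenomicInterval
from lfsn.network import (
    assemble,
    chromosome_colocalization,
    clique_communities,
    degree_difference_test,
    fit_power_law,
    hubs,
    module_participation,
    sample_discrete_power_law,
    set_enrichment_test,
    threshold_network,
    wilcoxon_rank_sum,
)


def _cand(pair, term="T", genes=("g1", "g2", "g3"), passed=True):
    res = EnrichmentResult(term, 3, 10, 3, 100, 1e-6)
    return CandidateModule(frozenset(pair), term, frozenset(genes), res, 1e-6,
                           topology_pass=passed)


class TestAssemble:
    def test_weight_counts_passing_modules(self):
        cands = [_cand(("A", "B"), term=t) for t in ("T1", "T2", "T3")]
        g = assemble(cands)
        assert g.number_of_edges() == 1
        assert g["A"]["B"]["weight"] == 3

    def test_failing_candidates_excluded(self):
        g = assemble([_cand(("A", "B"), passed=False), _cand(("C", "D"), passed=None)])
        assert g.number_of_edges() == 0

    def test_order_invariance(self):
        cands = [_cand(("A", "B"), term="T1"), _cand(("B", "C"), term="T2"),
                 _cand(("A", "B"), term="T3")]
        g1 = assemble(cands)
        g2 = assemble(cands[::-1])
        assert nx.utils.graphs_equal(g1, g2)


class TestPowerLaw:
    def test_parameter_recovery(self):
        xs = sample_discrete_power_law(2.5, 5000, rng=3)
        fit = fit_power_law(xs)
        assert 2.3 <= fit.alpha <= 2.7

    def test_degenerate_degrees_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_power_law([d for _, d in nx.complete_graph(10).degree()])

    def test_order_invariance(self):
        xs = sample_discrete_power_law(2.2, 500, rng=1)
        a = fit_power_law(xs)
        b = fit_power_law(xs[::-1])
        assert a == b


class TestHubs:
    def test_ceil_of_fraction(self):
        g = nx.path_graph(20)
        assert len(hubs(g)) == 2

    def test_star_center(self):
        g = nx.star_graph(9)  # center 0, leaves 1..9
        assert hubs(g) == {0}

    def test_tie_break_lexicographic(self):
        g = nx.cycle_graph([f"n{i}" for i in range(10)])  # all degree 2
        assert hubs(g) == {"n0"}

    def test_weighted_and_unweighted_agree_at_unit_weights(self):
        g = nx.barabasi_albert_graph(30, 2, seed=0)
        nx.set_edge_attributes(g, 1, "weight")
        assert hubs(g) == hubs(g, weighted=True)


def brute_force_clique_communities(g, k):
    """Independent oracle: enumerate all k-cliques, join those sharing k-1
    nodes, take components of the clique-adjacency graph."""
    nodes = sorted(g.nodes())
    cliques = [frozenset(c) for c in itertools.combinations(nodes, k)
               if all(g.has_edge(u, v) for u, v in itertools.combinations(c, 2))]
    parent = list(range(len(cliques)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(cliques)), 2):
        if len(cliques[i] & cliques[j]) == k - 1:
            parent[find(i)] = find(j)
    groups = {}
    for i, c in enumerate(cliques):
        groups.setdefault(find(i), set()).update(c)
    return {frozenset(m) for m in groups.values()}


class TestCliqueCommunities:
    def test_two_triangles_sharing_edge_merge(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("b", "d"), ("c", "d")])
        mods = clique_communities(g, 3)
        assert len(mods) == 1 and mods[0].members == {"a", "b", "c", "d"}

    def test_two_triangles_sharing_node_stay_separate(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                      ("c", "d"), ("d", "e"), ("c", "e")])
        mods = clique_communities(g, 3)
        assert {m.members for m in mods} == {frozenset("abc"), frozenset("cde")}

    def test_k_above_max_clique_empty(self):
        g = nx.cycle_graph(6)
        assert clique_communities(g, 3) == []

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("k", [3, 4])
    def test_matches_brute_force_oracle(self, seed, k):
        g = nx.gnp_random_graph(11, 0.4, seed=seed)
        got = {m.members for m in clique_communities(g, k)}
        assert got == brute_force_clique_communities(g, k)

    def test_every_member_in_a_k_clique(self):
        g = nx.gnp_random_graph(12, 0.45, seed=3)
        for mod in clique_communities(g, 3):
            sub = g.subgraph(mod.members)
            for v in mod.members:
                in_triangle = any(sub.has_edge(u, w)
                                  for u, w in itertools.combinations(sub[v], 2))
                assert in_triangle

    def test_module_participation_fraction(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y")])
        assert module_participation(g, 3) == pytest.approx(3 / 5)


class TestThresholdNetwork:
    def test_weight_gradient(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=3)
        g.add_edge("b", "c", weight=1)
        t = threshold_network(g, 2)
        assert set(map(frozenset, t.edges())) == {frozenset(("a", "b"))}
        assert set(t.nodes()) == {"a", "b", "c"}


class TestColocalization:
    def _coords(self, spec):
        return [GenomicInterval(n, c, s, e) for n, c, s, e in spec]

    def test_all_close_pairs(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        coords = self._coords([("a", "chr1", 100, 200), ("b", "chr1", 500_000, 500_100),
                               ("c", "chr1", 900_000, 900_100)])
        rep = chromosome_colocalization(g, coords, n_perm=10, seed=0)
        assert rep.frac_same_chr == 1.0 and rep.frac_within_window == 1.0

    def test_different_chromosomes(self):
        g = nx.Graph([("a", "b")])
        coords = self._coords([("a", "chr1", 100, 200), ("b", "chr2", 100, 200)])
        rep = chromosome_colocalization(g, coords, n_perm=10, seed=0)
        assert rep.frac_same_chr == 0.0 and rep.frac_within_window == 0.0

    def test_window_is_strict(self):
        g = nx.Graph([("a", "b")])
        coords = self._coords([("a", "chr1", 0, 100), ("b", "chr1", 100 + 10_000_000, 200 + 10_000_000)])
        rep = chromosome_colocalization(g, coords, n_perm=5, seed=0)
        assert rep.frac_same_chr == 1.0 and rep.frac_within_window == 0.0

    def test_missing_coordinates_excluded(self):
        g = nx.Graph([("a", "b"), ("a", "zz")])
        coords = self._coords([("a", "chr1", 0, 100), ("b", "chr1", 50, 150)])
        rep = chromosome_colocalization(g, coords, n_perm=5, seed=0)
        assert rep.n_pairs == 1 and rep.n_excluded == 1

    def test_no_located_edges_rejected(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(ValueError, match="coordinates"):
            chromosome_colocalization(g, [], n_perm=5, seed=0)


def exact_ranksum_two_sided(x, y):
    """Exhaustive enumeration of the rank-sum null for small tie-free samples."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    n = len(x)
    sums = [sum(c) for c in itertools.combinations(range(1, len(pooled) + 1), n)]
    mean = (n * (len(pooled) + 1)) / 2
    dev = abs(obs - mean)
    extreme = sum(1 for s in sums if abs(s - mean) >= dev - 1e-12)
    return extreme / len(sums)


class TestDegreeTests:
    def test_matches_exact_enumeration_oracle(self):
        x, y = [5.0, 6.0], [1.0, 2.0]
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(exact_ranksum_two_sided(x, y), abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_branch_matches_oracle_on_random_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.permutation(20)[:8].astype(float).tolist()
        x, y = vals[:4], vals[4:]
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(exact_ranksum_two_sided(x, y), abs=1e-10)

    def test_identical_degree_multisets_p_one(self):
        g = nx.Graph([("a", "b"), ("c", "d")])  # all degree 1
        _, p = degree_difference_test(g, {"a", "c"})
        assert p == pytest.approx(1.0)

    def test_calibration_under_random_special_sets(self):
        g = nx.barabasi_albert_graph(60, 2, seed=0)
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            special = rng.choice(60, size=10, replace=False)
            _, p = degree_difference_test(g, set(special.tolist()))
            ps.append(p)
        # under the null, roughly 5% of p-values fall below 0.05
        assert abs(np.mean(np.array(ps) < 0.05) - 0.05) < 0.06

    def test_empty_group_rejected(self):
        g = nx.path_graph(4)
        with pytest.raises(ValueError, match="nonempty"):
            degree_difference_test(g, set(g.nodes()))


def exact_fisher_two_sided(a, b, c, d):
    """Enumeration oracle: sum hypergeometric probabilities of tables (same
    margins) no more probable than the observed one."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    den = comb(n, c1)

    def prob(aa):
        return Fraction(comb(r1, aa) * comb(r2, c1 - aa), den)

    obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum(prob(aa) for aa in range(lo, hi + 1) if prob(aa) <= obs)
    return float(total)


class TestSetEnrichment:
    def test_matches_enumeration_oracle(self):
        universe = [f"u{i}" for i in range(8)]
        special = universe[:4]
        target = universe[3:4] + universe[6:8]  # a=1,b=3,c=2,d=2
        rec = set_enrichment_test(universe, special, target)
        a, b = rec.table[0]
        c, d = rec.table[1]
        assert rec.p == pytest.approx(exact_fisher_two_sided(a, b, c, d), abs=1e-10)

    def test_disjoint_sets_counts(self):
        universe = [f"u{i}" for i in range(20)]
        special = universe[:5]
        target = universe[5:10]
        rec = set_enrichment_test(universe, special, target)
        assert rec.table == ((0, 5), (5, 10))
        assert rec.p == pytest.approx(exact_fisher_two_sided(0, 5, 5, 10), abs=1e-10)

    def test_degenerate_all_equal(self):
        u = ["a", "b"]
        rec = set_enrichment_test(u, u, u)
        assert rec.degenerate and rec.p == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            set_enrichment_test([], [], [])
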