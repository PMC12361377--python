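"""Co-occurrence statistics, network construction and guild clustering."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import sagmetab as sm


def enumeration_tail(N, n_a, n_b, k):
    """Oracle: census of all C(N, n_b) draws of the second function."""
    marked = set(range(n_a))
    total = 0
    ge = 0
    for draw in itertools.combinations(range(N), n_b):
        total += 1
        if len(marked & set(draw)) >= k:
            ge += 1
    return ge / total


class TestHypergeomTail:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((4, 2, 2, 2), 1 / 6),           # C(2,2)C(2,0)/C(4,2)
            ((10, 5, 4, 4), 5 / 210),        # exhaustive placement census
            ((10, 5, 4, 0), 1.0),            # whole support
            ((6, 6, 3, 3), 1.0),             # forced overlap
        ],
    )
    def test_hand_and_enumeration_values(self, args, expected):
        assert sm.hypergeom_tail(*args) == pytest.approx(expected)

    def test_matches_enumeration_for_all_small_parameter_sets(self):
        for N in range(1, 13):
            for n_a in range(N + 1):
                for n_b in range(N + 1):
                    lo = max(0, n_a + n_b - N)
                    hi = min(n_a, n_b)
                    for k in range(lo, hi + 1):
                        got = sm.hypergeom_tail(N, n_a, n_b, k)
                        want = enumeration_tail(N, n_a, n_b, k)
                        assert got == pytest.approx(want, abs=1e-12), \
                            (N, n_a, n_b, k)

    def test_matches_scipy_at_larger_sizes(self):
        from scipy.stats import hypergeom

        rng = np.random.default_rng(4)
        for _ in range(50):
            N = int(rng.integers(20, 500))
            n_a = int(rng.integers(1, N))
            n_b = int(rng.integers(1, N))
            k = int(rng.integers(max(0, n_a + n_b - N), min(n_a, n_b) + 1))
            want = float(hypergeom.sf(k - 1, N, n_a, n_b))
            assert sm.hypergeom_tail(N, n_a, n_b, k) == pytest.approx(
                want, rel=1e-9, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            sm.hypergeom_tail(10, 3, 4, 5)
        with pytest.raises(ValueError):
            sm.hypergeom_tail(10, 11, 4, 2)


def profile_frame(columns):
    return pd.DataFrame(columns)


class TestBuildNetwork:
    def test_identical_profiles_strongly_linked(self):
        present = [1] * 5 + [0] * 15
        m = profile_frame({"fA": present, "fB": present})
        net = sm.build_network(m)
        assert net.graph.has_edge("fA", "fB")
        edge = net.edges.iloc[0]
        assert edge.p_value == pytest.approx(1 / math.comb(20, 5))
        assert edge.retained

    def test_single_function_has_no_edges(self):
        net = sm.build_network(profile_frame({"only": [1, 0, 1]}))
        assert net.graph.number_of_edges() == 0

    def test_degenerate_marginals_tested_but_never_significant(self):
        m = profile_frame({"always": [1] * 10, "never": [0] * 10,
                           "mixed": [1] * 5 + [0] * 5})
        net = sm.build_network(m)
        assert len(net.edges) == 3
        assert net.graph.number_of_edges() == 0

    def test_null_false_positive_budget(self):
        # independent profiles: expected false edges <= M * threshold
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.random((200, 10)) < 0.3)
        m.columns = [f"f{i}" for i in range(10)]
        net = sm.build_network(m.astype(int), e_threshold=0.1)
        assert net.graph.number_of_edges() <= math.ceil(45 * 0.1) + 2

    def test_multiplicity_none_uses_raw_p(self):
        present = [1] * 3 + [0] * 7
        m = profile_frame({"a": present, "b": present, "c": [0] * 10})
        raw = sm.build_network(m, multiplicity="none")
        scaled = sm.build_network(m, multiplicity="pairs")
        e_raw = raw.edges.set_index(["function_a", "function_b"])["e_value"]
        e_scaled = scaled.edges.set_index(
            ["function_a", "function_b"])["e_value"]
        assert np.allclose(e_scaled.to_numpy(), 3 * e_raw.to_numpy())

    def test_genome_order_invariance(self, rng):
        m = pd.DataFrame((rng.random((50, 6)) < 0.4).astype(int),
                         columns=list("abcdef"))
        net1 = sm.build_network(m)
        net2 = sm.build_network(m.sample(frac=1, random_state=3))
        pd.testing.assert_frame_equal(net1.edges, net2.edges)


class TestClusterGuilds:
    def _net_from_edges(self, edges, nodes=()):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return sm.GuildNetwork(graph=g, edges=pd.DataFrame(),
                               e_threshold=0.1, multiplicity=1)

    def test_two_disjoint_cliques_are_two_guilds(self):
        c1 = list(itertools.combinations(["a1", "a2", "a3", "a4"], 2))
        c2 = list(itertools.combinations(["b1", "b2", "b3", "b4"], 2))
        part = sm.cluster_guilds(self._net_from_edges(c1 + c2))
        assert len(set(part.values())) == 2
        assert len({part[n] for n in ["a1", "a2", "a3", "a4"]}) == 1
        assert len({part[n] for n in ["b1", "b2", "b3", "b4"]}) == 1

    def test_single_clique_is_one_guild(self):
        edges = list(itertools.combinations(["x1", "x2", "x3", "x4", "x5"], 2))
        part = sm.cluster_guilds(self._net_from_edges(edges))
        assert set(part.values()) == {"guild_1"}

    def test_isolated_nodes_left_unassigned(self):
        part = sm.cluster_guilds(
            self._net_from_edges([("a", "b")], nodes=["a", "b", "lonely"]))
        assert "lonely" not in part

    def test_empty_network_gives_empty_partition(self):
        part = sm.cluster_guilds(self._net_from_edges([], nodes=["a"]))
        assert part == {}

    def test_greedy_alternative_agrees_on_cliques(self):
        c1 = list(itertools.combinations(["a1", "a2", "a3"], 2))
        c2 = list(itertools.combinations(["b1", "b2", "b3"], 2))
        net = self._net_from_edges(c1 + c2)
        ecc = sm.cluster_guilds(net, method="ecc")
        greedy = sm.cluster_guilds(net, method="greedy")
        from sklearn.metrics import rand_score

        nodes = sorted(net.graph.nodes)
        assert rand_score([ecc[n] for n in nodes],
                          [greedy[n] for n in nodes]) == 1.0


def test_planted_two_guild_community_recovered(catalog):
    """End-to-end: planted guilds come back with Rand index >= 0.9."""
    from sklearn.metrics import rand_score

    guild_a = ("emp_glycolysis", "tca_cycle", "cyt_aa3", "co_oxidation")
    guild_b = ("cbb_cycle", "cyt_cbb3", "sox_complex", "rdsr")
    cfg = sm.CommunityConfig(
        n_genomes_per_habitat=100, multi_copy_fraction=0.0, seed=5,
        guilds=(sm.GuildSpec("A", guild_a, 0.4, 0.03),
                sm.GuildSpec("B", guild_b, 0.4, 0.03)),
    )
    truth, genomes = sm.generate_complete_genomes(cfg, catalog)
    profiles = {g: genomes[g].ko_counts() for g in genomes}
    matrix = sm.call_all(profiles, catalog)[list(guild_a + guild_b)]
    net = sm.build_network(matrix)
    part = sm.cluster_guilds(net)
    labels_true = [0] * 4 + [1] * 4
    labels_pred = [part.get(f, f"iso_{f}") for f in guild_a + guild_b]
    assert rand_score(labels_true, labels_pred) >= 0.9
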