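import math

import numpy as np
import pytest

from cohortnet.io import WeeklyNetwork, simplify
from cohortnet.mapeq import (
    Partition,
    description_length,
    detect_communities,
    modularity,
    run_stability,
    visit_frequencies,
)

from _oracles import (
    codelength_dense,
    exhaustive_min_codelength,
    modularity_direct,
    stationary_dense,
)
from conftest import bidirected_clique, net_from

TAU = 0.15


class TestVisitFrequencies:
    def test_directed_cycle_is_uniform(self):
        net = net_from(1, [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        vis = visit_frequencies(net, tau=0.3)
        assert np.allclose(vis.p, 0.25, atol=1e-10)

    def test_single_isolated_node(self):
        net = simplify(WeeklyNetwork.from_edges(1, [("A", "A")]))
        vis = visit_frequencies(net, tau=TAU)
        assert vis.p.tolist() == [1.0]

    def test_chain_matches_dense_linear_solve(self):
        edges = [("A", "B"), ("B", "C")]
        net = net_from(1, edges)
        vis = visit_frequencies(net, tau=TAU)
        nodes, p_ref = stationary_dense(net.nodes, edges, TAU)
        assert tuple(nodes) == vis.nodes
        assert np.allclose(vis.p, p_ref, atol=1e-9)

    def test_sums_to_one_on_synthetic(self, small_cohort):
        _, _, nets = small_cohort
        for net in nets:
            vis = visit_frequencies(net, tau=TAU)
            assert abs(vis.p.sum() - 1.0) < 1e-12
            assert (vis.p >= 0).all()

    def test_bad_tau_rejected(self, toy_weeks):
        with pytest.raises(ValueError):
            visit_frequencies(toy_weeks[0], tau=0.0)


class TestDescriptionLength:
    def test_one_module_equals_visit_entropy(self, two_cliques_net):
        vis = visit_frequencies(two_cliques_net, tau=TAU)
        rep = description_length(two_cliques_net, Partition.one_module(two_cliques_net.nodes), visit=vis)
        entropy = -sum(p * math.log2(p) for p in vis.p)
        assert rep.q_total == pytest.approx(0.0, abs=1e-12)
        assert rep.total == pytest.approx(entropy, abs=1e-10)

    def test_uniform_four_nodes_one_module_is_two_bits(self):
        net = net_from(1, [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])
        rep = description_length(net, Partition.one_module(net.nodes), tau=TAU)
        assert rep.total == pytest.approx(2.0, abs=1e-10)

    def test_joined_cliques_match_formula_oracle(self):
        edges = bidirected_clique(["a1", "a2", "a3", "a4"]) + bidirected_clique(
            ["b1", "b2", "b3", "b4"]
        ) + [("a1", "b1")]
        net = net_from(1, edges)
        mapping = {n: (0 if n.startswith("a") else 1) for n in net.nodes}
        rep = description_length(net, Partition(mapping), tau=TAU)
        ref = codelength_dense(net.nodes, edges, TAU, mapping)
        assert rep.total == pytest.approx(ref, abs=1e-9)

    def test_all_terms_nonnegative_and_bounded_below_by_nothing_less_than_entropy(
        self, small_cohort
    ):
        _, _, nets = small_cohort
        net = nets[0]
        vis = visit_frequencies(net, tau=TAU)
        part, rep = detect_communities(net, tau=TAU, n_runs=3, seed=0, visit=vis)
        assert rep.index_term >= 0
        assert all(t >= -1e-12 for t in rep.module_terms.values())
        one = description_length(net, Partition.one_module(net.nodes), visit=vis)
        singles = description_length(net, Partition.singletons(net.nodes), visit=vis)
        assert rep.total <= one.total + 1e-12
        assert rep.total <= singles.total + 1e-12


class TestDetectCommunities:
    def test_two_disconnected_cliques_exact_optimum(self, two_cliques_net):
        part, rep = detect_communities(two_cliques_net, tau=TAU, n_runs=10, seed=1)
        blocks = set(part.communities().values())
        assert blocks == {("a1", "a2", "a3", "a4"), ("b1", "b2", "b3", "b4")}
        best_L, _ = exhaustive_min_codelength(two_cliques_net.nodes, two_cliques_net.edges, TAU)
        assert rep.total == pytest.approx(best_L, abs=1e-9)

    def test_complete_digraph_one_module_optimal(self):
        net = net_from(1, bidirected_clique("ABCDEF"))
        part, rep = detect_communities(net, tau=TAU, n_runs=5, seed=0)
        assert part.n_communities == 1
        best_L, _ = exhaustive_min_codelength(net.nodes, net.edges, TAU)
        assert rep.total == pytest.approx(best_L, abs=1e-9)

    def test_deterministic_given_seed(self, small_cohort):
        _, _, nets = small_cohort
        p1, r1 = detect_communities(nets[0], tau=TAU, n_runs=3, seed=42)
        p2, r2 = detect_communities(nets[0], tau=TAU, n_runs=3, seed=42)
        assert p1 == p2 and r1.total == r2.total

    def test_agrees_with_igraph_on_clear_structure(self):
        igraph = pytest.importorskip("igraph")
        edges = (
            bidirected_clique(["a1", "a2", "a3", "a4", "a5"])
            + bidirected_clique(["b1", "b2", "b3", "b4", "b5"])
            + [("a1", "b1"), ("b2", "a2")]
        )
        net = net_from(1, edges)
        part, _ = detect_communities(net, tau=TAU, n_runs=10, seed=0)
        nodes = sorted(net.nodes)
        g = igraph.Graph(directed=True)
        g.add_vertices(nodes)
        g.add_edges(list(net.edge_set))
        ref = g.community_infomap()
        ref_blocks = {tuple(sorted(nodes[i] for i in c)) for c in ref}
        assert set(part.communities().values()) == ref_blocks


class TestModularity:
    def test_matches_direct_double_sum(self, small_cohort):
        _, _, nets = small_cohort
        net = nets[0]
        part, _ = detect_communities(net, tau=TAU, n_runs=2, seed=0)
        assert modularity(net, part) == pytest.approx(
            modularity_direct(net.nodes, net.edge_set, part.mapping), abs=1e-10
        )

    def test_one_module_value(self, two_cliques_net):
        net = two_cliques_net
        part = Partition.one_module(net.nodes)
        assert modularity(net, part) == pytest.approx(
            modularity_direct(net.nodes, net.edge_set, part.mapping), abs=1e-12
        )

    def test_two_equal_cliques_half(self, two_cliques_net):
        mapping = {n: n[0] for n in two_cliques_net.nodes}
        assert modularity(two_cliques_net, Partition(mapping)) == pytest.approx(0.5)

    def test_singleton_partition_nonpositive(self, toy_weeks):
        net = toy_weeks[2]
        assert modularity(net, Partition.singletons(net.nodes)) <= 0

    def test_zero_edges_rejected(self):
        net = simplify(WeeklyNetwork.from_edges(1, [("A", "A")]))
        with pytest.raises(ValueError):
            modularity(net, Partition.one_module(net.nodes))


class TestRunStability:
    def test_unambiguous_optimum_gives_zero_vi(self, two_cliques_net):
        res = run_stability(two_cliques_net, tau=TAU, n_pairs=3, seed=0)
        assert res.vi_mean == pytest.approx(0.0, abs=1e-12)
        assert res.mean_n_communities == pytest.approx(2.0)

    def test_single_pair_has_undefined_sem(self, two_cliques_net):
        res = run_stability(two_cliques_net, tau=TAU, n_pairs=1, seed=0)
        assert math.isnan(res.vi_sem)

    def test_planted_blocks_small_vi_relative_to_bound(self):
        rng = np.random.default_rng(5)
        blocks = [[f"{c}{i}" for i in range(6)] for c in "abcd"]
        edges = []
        for block in blocks:
            for a in block:
                for b in block:
                    if a != b and rng.random() < 0.8:
                        edges.append((a, b))
        all_nodes = [n for b in blocks for n in b]
        for _ in range(20):  # sparse noise between blocks
            a, b = rng.choice(all_nodes, size=2, replace=False)
            edges.append((a, b))
        net = net_from(1, edges)
        res = run_stability(net, tau=TAU, n_pairs=10, seed=0)
        assert res.vi_mean < 0.1 * math.log2(net.n_nodes)
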