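import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import riskgraph as rg
from riskgraph.reconstruction import EdgeWeightParams, domain_edge_weights, shortest_path_union

from conftest import make_annotated


class TestEdgeWeight:
    def test_minimum_zero(self):
        assert rg.reconstruction_edge_weight(5, 5, True, True) == 0.0

    def test_maximum_fifteen(self):
        assert rg.reconstruction_edge_weight(0, 0, False, False) == 15.0

    def test_one_annotated_hand_value(self):
        assert rg.reconstruction_edge_weight(3.0, 4.0, True, False) == pytest.approx(6.0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            rg.reconstruction_edge_weight(5.1, 0, True, True)
        with pytest.raises(ValueError):
            rg.reconstruction_edge_weight(0, -0.1, True, True)

    def test_params_invariants(self):
        with pytest.raises(ValueError):
            EdgeWeightParams(penalty_both=4, penalty_one=3)
        assert EdgeWeightParams().weight_max == 15.0

    @given(
        trs=st.floats(min_value=0, max_value=5),
        lower=st.floats(min_value=0, max_value=5),
        other=st.floats(min_value=0, max_value=5),
        flags=st.tuples(st.booleans(), st.booleans()),
    )
    @settings(max_examples=100, deadline=None)
    def test_lowering_risk_never_decreases_weight(self, trs, lower, other, flags):
        low = min(trs, lower)
        w_hi = rg.reconstruction_edge_weight(trs, other, *flags)
        w_lo = rg.reconstruction_edge_weight(low, other, *flags)
        assert w_lo >= w_hi - 1e-12


def brute_force_best_path(g, weights, a, b):
    """Oracle: enumerate all simple paths; min cost, then lexicographic path."""
    best = None
    for path in nx.all_simple_paths(g, a, b):
        cost = sum(weights[tuple(sorted(e))] for e in zip(path, path[1:]))
        key = (cost, tuple(path))
        if best is None or key < best:
            best = key
    return best


class TestShortestPathUnion:
    def test_single_edge_pair(self):
        g = nx.Graph([("A", "B")])
        union, paths = shortest_path_union(g, ["A", "B"], {("A", "B"): 1.0})
        assert set(union.nodes) == {"A", "B"} and union.number_of_edges() == 1
        assert paths[("A", "B")] == (1.0, ("A", "B"))

    def test_indirect_path_beats_expensive_direct_edge(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        weights = {("A", "B"): 2.0, ("B", "C"): 2.0, ("A", "C"): 9.0}
        union, paths = shortest_path_union(g, ["A", "C"], weights)
        assert set(union.nodes) == {"A", "B", "C"}
        assert {tuple(sorted(e)) for e in union.edges} == {("A", "B"), ("B", "C")}
        assert paths[("A", "C")] == (4.0, ("A", "B", "C"))

    def test_oracle_equivalence_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
            weights = {tuple(sorted(e)): float(rng.integers(1, 5)) for e in g.edges}
            seeds = sorted(str(s) for s in rng.choice(sorted(g.nodes), size=min(3, n), replace=False))
            union, paths = shortest_path_union(g, seeds, weights)
            expected_nodes, expected_edges = set(seeds), set()
            for a, b in itertools.combinations(seeds, 2):
                best = brute_force_best_path(g, weights, a, b)
                if best is None:
                    assert (a, b) not in paths
                    continue
                cost, path = best
                assert paths[(a, b)][0] == pytest.approx(cost)
                assert paths[(a, b)][1] == path
                expected_nodes |= set(path)
                expected_edges |= {tuple(sorted(e)) for e in zip(path, path[1:])}
            assert set(union.nodes) == expected_nodes
            assert {tuple(sorted(e)) for e in union.edges} == expected_edges

    def test_zero_weight_edges_handled(self):
        g = nx.path_graph(["A", "B", "C", "D"])
        weights = {("A", "B"): 0.0, ("B", "C"): 0.0, ("C", "D"): 0.0}
        _, paths = shortest_path_union(g, ["A", "D"], weights)
        assert paths[("A", "D")] == (0.0, ("A", "B", "C", "D"))

    def test_negative_weight_rejected(self):
        g = nx.Graph([("A", "B")])
        with pytest.raises(ValueError):
            shortest_path_union(g, ["A", "B"], {("A", "B"): -1.0})


class TestBuildDomainGraph:
    def _toy_net(self):
        # A - B - C chain plus expensive detour A - X - C
        return make_annotated(
            {
                "A": (5.0, ["D"]),
                "B": (5.0, ["D"]),
                "C": (5.0, ["D"]),
                "X": (0.0, []),
            },
            [("A", "B", 2), ("B", "C", 2), ("A", "X", 2), ("X", "C", 2)],
        )

    def test_both_seeds_input_provenance(self):
        net = make_annotated({"A": (1, ["D"]), "B": (1, ["D"])}, [("A", "B", 2)])
        bg = rg.build_domain_graph(net, {"A", "B"}, "D")
        assert bg.n_nodes == 2 and bg.n_edges == 1
        assert {d["provenance"] for _, d in bg.graph.nodes(data=True)} == {"input"}

    def test_intermediate_node_added_with_provenance(self):
        bg = rg.build_domain_graph(self._toy_net(), {"A", "C"}, "D")
        assert set(bg.graph.nodes) == {"A", "B", "C"}
        assert bg.graph.nodes["B"]["provenance"] == "added_in_domain"
        assert bg.graph.nodes["A"]["provenance"] == "input"

    def test_out_of_domain_provenance(self):
        net = make_annotated(
            {"A": (5.0, ["D"]), "B": (5.0, []), "C": (5.0, ["D"])},
            [("A", "B", 2), ("B", "C", 2)],
        )
        bg = rg.build_domain_graph(net, {"A", "C"}, "D")
        assert bg.graph.nodes["B"]["provenance"] == "added_out_domain"

    def test_disconnected_seeds_retained_isolated(self):
        net = make_annotated(
            {"A": (1, []), "B": (1, []), "Z": (1, []), "Y": (1, [])},
            [("A", "B", 2), ("Z", "Y", 2)],
        )
        bg = rg.build_domain_graph(net, {"A", "Z"}, "D")
        assert set(bg.graph.nodes) == {"A", "Z"}
        assert bg.n_edges == 0
        assert nx.number_connected_components(bg.graph) >= 2

    def test_empty_seed_set_raises(self):
        with pytest.raises(ValueError):
            rg.build_domain_graph(self._toy_net(), set(), "D")

    def test_absent_seeds_warn_and_excluded(self, caplog):
        net = self._toy_net()
        with caplog.at_level("WARNING"):
            bg = rg.build_domain_graph(net, {"A", "C", "MISSING"}, "D")
        assert "MISSING" not in bg.graph
        assert bg.seeds == ("A", "C")

    def test_seed_order_invariance(self, filtered, bundle):
        _, catalog, truth = bundle
        seeds = sorted(filtered.graph.nodes)[:25]
        bg1 = rg.build_domain_graph(filtered, seeds, "Domain01")
        bg2 = rg.build_domain_graph(filtered, list(reversed(seeds)), "Domain01")
        assert set(bg1.graph.nodes) == set(bg2.graph.nodes)
        assert set(map(frozenset, bg1.graph.edges)) == set(map(frozenset, bg2.graph.edges))

    def test_hop_distances(self):
        bg = rg.build_domain_graph(self._toy_net(), {"A", "C"}, "D")
        assert bg.graph.nodes["A"]["hop_distance"] == 0
        assert bg.graph.nodes["C"]["hop_distance"] == 0
        assert bg.graph.nodes["B"]["hop_distance"] == 1

    def test_edges_exist_in_base(self, filtered):
        seeds = sorted(filtered.graph.nodes)[:20]
        bg = rg.build_domain_graph(filtered, seeds, "Domain01")
        for u, v in bg.graph.edges:
            assert filtered.graph.has_edge(u, v)

    def test_weights_match_formula(self, filtered):
        weights = domain_edge_weights(filtered, "Domain01")
        for (u, v), w in list(weights.items())[:50]:
            expected = rg.reconstruction_edge_weight(
                filtered.risk(u),
                filtered.risk(v),
                "Domain01" in filtered.biodomains(u),
                "Domain01" in filtered.biodomains(v),
            )
            assert w == pytest.approx(expected)


class TestTermCoverage:
    def test_half(self):
        graph = nx.path_graph([f"g{i}" for i in range(4)])
        term = [f"g{i}" for i in range(2)] + ["x1", "x2", "x3", "x4", "x5", "x6"]
        assert rg.term_coverage(term, graph) == pytest.approx(2 / 8)

    def test_full_and_none(self):
        graph = nx.path_graph(["a", "b", "c"])
        assert rg.term_coverage(["a", "b"], graph) == 1.0
        assert rg.term_coverage(["x", "y"], graph) == 0.0

    def test_empty_term_raises(self):
        with pytest.raises(ValueError):
            rg.term_coverage([], nx.path_graph(["a", "b"]))
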