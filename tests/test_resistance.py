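"""Resistance-distance validation on the reaction-compound graph."""

import networkx as nx
import numpy as np
import pytest

import heatpath as hp
from heatpath import resistance as rd


def rc_from_nx(g, order=None):
    return rd.ReactionCompoundGraph(g, order or list(g.nodes()))


def alternating_graph(edges):
    """Build a reaction/compound graph from an edge list on string ids.

    Ids starting with 'r' become reactions, everything else compounds.
    """
    g = nx.Graph()
    for u, v in edges:
        for n in (u, v):
            if n not in g:
                g.add_node(n, level="reaction" if n.startswith("r") else "compound")
        g.add_edge(u, v)
    return g


class TestExtraction:
    def test_chain_strips_pathway(self, chain_graph):
        rc = hp.reaction_compound_graph(chain_graph)
        assert set(rc.node_ids) == {"c", "r"}
        assert rc.graph.number_of_edges() == 1

    def test_largest_island_kept(self):
        g = nx.Graph()
        for n, lv in [("c1", "compound"), ("r1", "reaction"), ("c2", "compound"),
                      ("r2", "reaction"), ("c3", "compound"), ("r3", "reaction"),
                      ("p", "pathway")]:
            g.add_node(n, level=lv)
        g.add_edges_from([("c1", "r1"), ("r1", "c2"), ("c2", "r2")])  # island of 4
        g.add_edges_from([("c3", "r3")])  # island of 2
        g.add_edges_from([("r2", "p"), ("r3", "p")])  # connected via pathway only
        rc = hp.reaction_compound_graph(hp.LevelledGraph(g))
        assert set(rc.node_ids) == {"c1", "r1", "c2", "r2"}

    def test_no_reactions_is_an_error(self, ora_toy):
        with pytest.raises(ValueError, match="no reaction nodes"):
            hp.reaction_compound_graph(ora_toy)


class TestResistanceDistance:
    def test_single_edge_is_unit_resistor(self):
        rc = rc_from_nx(alternating_graph([("c1", "r1")]))
        assert hp.resistance_distance(rc, "c1", "r1") == pytest.approx(1.0, abs=1e-10)

    def test_triangle_adjacent_nodes(self):
        # 1 Ohm in parallel with 2 Ohm: 2/3
        g = alternating_graph([("c1", "r1"), ("r1", "c2"), ("c2", "r1x")])
        g.add_edge("c1", "r1x")
        g.add_edge("c1", "r1")
        tri = nx.Graph()
        for n, lv in [("a", "compound"), ("b", "reaction"), ("c", "compound")]:
            tri.add_node(n, level=lv)
        tri.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
        rc = rc_from_nx(tri)
        assert hp.resistance_distance(rc, "a", "b") == pytest.approx(2 / 3, abs=1e-10)

    def test_three_path_ends_in_series(self):
        rc = rc_from_nx(alternating_graph([("c1", "r1"), ("r1", "c2")]))
        assert hp.resistance_distance(rc, "c1", "c2") == pytest.approx(2.0, abs=1e-10)

    def test_identity_and_symmetry(self):
        rc = rc_from_nx(alternating_graph([("c1", "r1"), ("r1", "c2"), ("c2", "r2"), ("r2", "c1")]))
        assert hp.resistance_distance(rc, "c1", "c1") == 0.0
        assert hp.resistance_distance(rc, "c1", "r2") == pytest.approx(
            hp.resistance_distance(rc, "r2", "c1"), abs=1e-12
        )

    def test_node_outside_graph_rejected(self):
        rc = rc_from_nx(alternating_graph([("c1", "r1")]))
        with pytest.raises(ValueError, match="zz"):
            hp.resistance_distance(rc, "c1", "zz")

    def test_pseudoinverse_equals_kirchhoff_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            g = nx.connected_watts_strogatz_graph(30, 4, 0.3, seed=trial)
            h = nx.Graph()
            for n in g.nodes():
                h.add_node(str(n), level="reaction" if n % 2 else "compound")
            for u, v in g.edges():
                h.add_edge(str(u), str(v))
            rc = rc_from_nx(h)
            for _ in range(5):
                i, j = rng.choice(30, 2, replace=False)
                a = hp.resistance_distance(rc, str(i), str(j), method="pinv")
                b = hp.resistance_distance(rc, str(i), str(j), method="grounded")
                assert a == pytest.approx(b, abs=1e-8)

    def test_equals_path_length_on_trees_and_bounded_by_it_generally(self):
        rng = np.random.default_rng(1)
        tree = nx.random_labeled_tree(20, seed=2)
        h = nx.Graph()
        for n in tree.nodes():
            h.add_node(str(n), level="reaction" if n % 2 else "compound")
        for u, v in tree.edges():
            h.add_edge(str(u), str(v))
        rc = rc_from_nx(h)
        sp = dict(nx.all_pairs_shortest_path_length(h))
        for _ in range(10):
            i, j = rng.choice(20, 2, replace=False)
            omega = hp.resistance_distance(rc, str(i), str(j))
            assert omega == pytest.approx(sp[str(i)][str(j)], abs=1e-9)

    def test_triangle_inequality_spot_check(self):
        g = nx.connected_watts_strogatz_graph(25, 4, 0.4, seed=9)
        h = nx.Graph()
        for n in g.nodes():
            h.add_node(str(n), level="reaction" if n % 2 else "compound")
        for u, v in g.edges():
            h.add_edge(str(u), str(v))
        rc = rc_from_nx(h)
        rng = np.random.default_rng(4)
        for _ in range(20):
            i, j, k = (str(x) for x in rng.choice(25, 3, replace=False))
            assert hp.resistance_distance(rc, i, j) <= (
                hp.resistance_distance(rc, i, k) + hp.resistance_distance(rc, k, j) + 1e-9
            )


class TestSummaries:
    def test_single_edge_summary(self):
        rc = rc_from_nx(alternating_graph([("c1", "r1")]))
        s = hp.reaction_distance_summary(rc, {"r1"}, {"c1"})
        assert s["mean"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        assert s["sd"].iloc[0] == 0.0

    def test_all_reactions_baseline_row(self, medium_graph):
        rc = hp.reaction_compound_graph(medium_graph)
        targets = set(rc.compounds()[:3])
        s = hp.reaction_distance_summary(rc, rc.reactions(), targets)
        assert len(s) == 3
        assert (s["n_reactions"] == len(rc.reactions())).all()
        assert (s["mean"] > 0).all()

    def test_absent_nodes_dropped_with_warning(self, medium_graph, caplog):
        rc = hp.reaction_compound_graph(medium_graph)
        with caplog.at_level("WARNING"):
            s = hp.reaction_distance_summary(rc, set(rc.reactions()[:4]) | {"zz"}, rc.compounds()[:2])
        assert (s["n_reactions"] == 4).all()
        assert "dropped" in caplog.text


class TestNeighbourComparison:
    def test_identical_sets_never_significant(self, medium_graph):
        rc = hp.reaction_compound_graph(medium_graph)
        inputs = rc.compounds()[:5]
        neigh = rd.neighbour_reactions(rc, inputs)
        out = hp.neighbour_comparison(rc, neigh, inputs, rc.compounds()[5:8])
        assert (out["p_value"] > 0.4).all()

    def test_perfect_separation_is_significant(self):
        # reported reactions adjacent to the target; neighbours far away
        edges = [("t", "ra1"), ("t", "ra2"), ("t", "ra3")]
        chain = [("ra3", "c0"), ("c0", "rb0")]
        for i in range(6):
            chain += [(f"rb{i}", f"cb{i}"), (f"cb{i}", f"rb{i+1}")]
        g = alternating_graph(edges + chain)
        for i in range(7):
            g.nodes[f"rb{i}"]["level"] = "reaction"
        g.nodes["t"]["level"] = "compound"
        rc = rc_from_nx(g)
        far_inputs = ["cb4", "cb5"]
        out = hp.neighbour_comparison(
            rc, ["ra1", "ra2", "ra3"], far_inputs, ["t"], adjust=False
        )
        assert (out["p_value"] < 0.05).all()
        assert (out["mean_reported"] < out["mean_neighbours"]).all()

    def test_validation_table_emits_all_solution_target_comparisons(self, medium_graph):
        # 4 solutions x 8 targets -> 32 BH-adjusted p-values
        rc = hp.reaction_compound_graph(medium_graph)
        rng = np.random.default_rng(0)
        reactions = rc.reactions()
        solutions = {
            f"solution {i}": [reactions[j] for j in rng.choice(len(reactions), 20, replace=False)]
            for i in range(4)
        }
        inputs = rc.compounds()[:10]
        targets = rc.compounds()[10:18]
        summary, tests = hp.validation_table(medium_graph, solutions, inputs, targets)
        assert len(tests) == 32
        assert tests["p_adjusted"].notna().all()
        # summary holds baseline + first neighbours + 4 solutions, per target
        assert len(summary) == 6 * 8

    def test_superset_mean_uses_larger_support(self, medium_graph):
        rc = hp.reaction_compound_graph(medium_graph)
        reactions = rc.reactions()
        small = set(reactions[:5])
        large = set(reactions[:25])
        t = {rc.compounds()[0]}
        s_small = hp.reaction_distance_summary(rc, small, t)
        s_large = hp.reaction_distance_summary(rc, large, t)
        assert s_large["n_reactions"].iloc[0] > s_small["n_reactions"].iloc[0]
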