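import networkx as nx
import numpy as np
import pytest
from scipy.special import comb

from conftest import brute_force_geodesics
from flyscreen import synth
from flyscreen.brainnet import (attribute_tables, connector_analysis,
                                enrich_connectors, export_graph,
                                random_seed_control)


def weighted(edges):
    graph = nx.Graph()
    for u, v in edges:
        graph.add_edge(u, v, weight=1.0)
    return graph


class TestConnectorAnalysis:
    def test_single_path_connector(self):
        result = connector_analysis(weighted([("a", "x"), ("x", "b")]),
                                    ["a", "b"])
        assert result.connectors == {"x"}
        assert result.edge_criticality == {("a", "x"): 1, ("b", "x"): 1}
        assert result.pair_geodesics[("a", "b")] == (2, 1)

    def test_four_cycle_has_two_geodesics(self):
        cycle = weighted([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        result = connector_analysis(cycle, ["a", "c"])
        assert result.connectors == {"b", "d"}
        assert result.pair_geodesics[("a", "c")] == (2, 2)
        assert set(result.edge_criticality.values()) == {1}

    def test_adjacent_seeds_contribute_no_connectors(self):
        result = connector_analysis(weighted([("a", "b"), ("b", "c")]),
                                    ["a", "b"])
        assert result.connectors == set()

    def test_seed_on_geodesic_is_not_a_connector(self):
        path = weighted([("a", "s"), ("s", "b")])
        result = connector_analysis(path, ["a", "s", "b"])
        assert result.connectors == set()
        assert result.pair_geodesics[("a", "b")] == (2, 1)

    def test_unmapped_seeds_reported_not_fatal(self):
        result = connector_analysis(weighted([("a", "x"), ("x", "b")]),
                                    ["a", "b", "ghost"])
        assert result.seeds_unmapped == ["ghost"]
        with pytest.raises(ValueError):
            connector_analysis(weighted([("a", "b")]), ["a", "ghost"])

    def test_disconnected_pairs_recorded(self):
        graph = weighted([("a", "b"), ("c", "d")])
        result = connector_analysis(graph, ["a", "c"])
        assert result.disconnected_pairs == [("a", "c")]

    def test_weight_cutoff_removes_weak_edges(self):
        graph = nx.Graph()
        graph.add_edge("a", "x", weight=0.9)
        graph.add_edge("x", "b", weight=0.9)
        graph.add_edge("a", "b", weight=0.1)  # direct but weak
        with_weak = connector_analysis(graph, ["a", "b"])
        assert with_weak.connectors == set()
        cut = connector_analysis(graph, ["a", "b"], weight_cutoff=0.5)
        assert cut.connectors == {"x"}

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(8, 31))
            net = synth.generate_network(
                n, {"kind": "erdos_renyi", "p": 2.2 * np.log(n) / n},
                int(rng.integers(3, 6)), 0.2, seed=int(rng.integers(2**31)))
            result = connector_analysis(net.graph, net.seeds)
            connectors, criticality, pairs = brute_force_geodesics(
                net.graph, net.seeds)
            assert result.connectors == connectors
            assert result.edge_criticality == criticality
            assert result.pair_geodesics == pairs

    def test_edge_count_identity(self):
        # total edge criticality equals sum over pairs of length * count
        net = synth.generate_network(40, {"kind": "erdos_renyi", "p": 0.12},
                                     5, 0.2, seed=9)
        result = connector_analysis(net.graph, net.seeds)
        assert sum(result.edge_criticality.values()) == sum(
            length * count for length, count in result.pair_geodesics.values())

    def test_invariant_to_node_relabeling(self):
        net = synth.generate_network(25, {"kind": "erdos_renyi", "p": 0.2},
                                     4, 0.2, seed=2)
        mapping = {node: f"relabel_{node}" for node in net.graph.nodes}
        relabeled = nx.relabel_nodes(net.graph, mapping)
        base = connector_analysis(net.graph, net.seeds)
        other = connector_analysis(relabeled,
                                   [mapping[s] for s in net.seeds])
        assert {mapping[c] for c in base.connectors} == other.connectors

    def test_removing_off_geodesic_edge_changes_nothing(self):
        net = synth.generate_network(30, {"kind": "erdos_renyi", "p": 0.2},
                                     4, 0.2, seed=5)
        base = connector_analysis(net.graph, net.seeds)
        on_geodesic = set(base.edge_criticality)
        off = next(e for e in (tuple(sorted(edge)) for edge in net.graph.edges)
                   if e not in on_geodesic)
        pruned = net.graph.copy()
        pruned.remove_edge(*off)
        if nx.is_connected(pruned):
            after = connector_analysis(pruned, net.seeds)
            assert after.connectors == base.connectors
            assert after.edge_criticality == base.edge_criticality


class TestEnrichment:
    def path_result(self, n_connectors=5):
        graph = weighted([("s1", f"c{i}") for i in range(n_connectors)]
                         + [(f"c{i}", "s2") for i in range(n_connectors)])
        return connector_analysis(graph, ["s1", "s2"]), graph

    def test_hypergeometric_point_mass(self):
        result, _ = self.path_result(5)
        background = {f"c{i}" for i in range(5)} | {f"b{i}" for i in range(15)}
        annotation = {f"c{i}" for i in range(5)}
        table = enrich_connectors(result, annotation, background=background)
        assert table.p == pytest.approx(1 / comb(20, 5), rel=1e-4)
        assert (table.a, table.b, table.c, table.d) == (5, 0, 0, 15)

    def test_equal_annotation_fraction_not_significant(self):
        result, _ = self.path_result(5)
        background = ({f"c{i}" for i in range(5)}
                      | {f"b{i}" for i in range(95)})
        annotation = {"c0", "c1"} | {f"b{i}" for i in range(38)}  # 40% both
        table = enrich_connectors(result, annotation, background=background)
        assert table.p > 0.05

    def test_zero_annotated_gives_p_one(self):
        result, _ = self.path_result(3)
        table = enrich_connectors(result, set(),
                                  background={f"b{i}" for i in range(10)})
        assert table.p == pytest.approx(1.0)
        assert not table.odds_ratio_defined

    def test_empty_connectors_rejected(self):
        graph = weighted([("a", "b")])
        result = connector_analysis(graph, ["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            enrich_connectors(result, {"a"})


class TestRandomSeedControl:
    def test_full_pool_draw_is_point_mass(self):
        net = synth.generate_network(30, {"kind": "erdos_renyi", "p": 0.2},
                                     4, 0.3, seed=11)
        base = connector_analysis(net.graph, net.seeds)
        expected = enrich_connectors(base, net.annotation)
        table, _ = random_seed_control(net.graph, net.seeds,
                                       k=len(net.seeds), n_iter=5,
                                       annotation=net.annotation, seed=0)
        assert np.allclose(table.p, expected.p)
        assert np.allclose(table.odds_ratio, expected.odds_ratio)

    def test_uniform_annotation_gives_null_odds_ratio_near_one(self):
        net = synth.generate_network(120, {"kind": "erdos_renyi", "p": 0.05},
                                     6, 0.3, seed=13)
        _, summary = random_seed_control(net.graph,
                                         sorted(net.graph.nodes), k=6,
                                         n_iter=100,
                                         annotation=net.annotation, seed=1)
        assert 0.5 < summary["median_odds_ratio"] < 2.0
        assert summary["n_ok"] > 80

    def test_seeded_determinism(self):
        net = synth.generate_network(40, {"kind": "erdos_renyi", "p": 0.15},
                                     4, 0.3, seed=17)
        t1, s1 = random_seed_control(net.graph, sorted(net.graph.nodes), 4,
                                     20, net.annotation, seed=7)
        t2, s2 = random_seed_control(net.graph, sorted(net.graph.nodes), 4,
                                     20, net.annotation, seed=7)
        assert t1.equals(t2) and s1 == s2

    def test_pool_too_small_rejected(self):
        net = synth.generate_network(10, {"kind": "erdos_renyi", "p": 0.4},
                                     2, 0.3, seed=19)
        with pytest.raises(ValueError):
            random_seed_control(net.graph, ["n0000"], 3, 5, set(), seed=0)


class TestExport:
    def test_path_graph_export(self):
        graph = weighted([("a", "x"), ("x", "b")])
        result = connector_analysis(graph, ["a", "b"])
        exported = export_graph(result, graph)
        assert sorted(exported.nodes) == ["a", "b", "x"]
        assert exported.number_of_edges() == 2
        assert all(d["criticality"] == 1
                   for _, _, d in exported.edges(data=True))
        assert exported.nodes["x"]["role"] == "connector"
        assert exported.nodes["a"]["role"] == "seed"

    def test_degree_attribute_matches_network(self):
        net = synth.generate_network(25, {"kind": "erdos_renyi", "p": 0.25},
                                     4, 0.2, seed=23)
        result = connector_analysis(net.graph, net.seeds)
        exported = export_graph(result, net.graph, net.annotation)
        for node, data in exported.nodes(data=True):
            assert data["degree"] == net.graph.degree(node)
            assert data["annotated"] == (node in net.annotation)

    def test_attributes_round_trip_through_graphml(self, tmp_path):
        from flyscreen import io

        graph = weighted([("a", "x"), ("x", "b")])
        result = connector_analysis(graph, ["a", "b"])
        exported = export_graph(result, graph)
        path = tmp_path / "graph.graphml"
        io.write_graphml(exported, path)
        reloaded = io.read_graphml(path)
        for node, data in exported.nodes(data=True):
            for key, value in data.items():
                assert reloaded.nodes[node][key] == value
        nodes, edges = attribute_tables(exported)
        assert len(nodes) == 3 and len(edges) == 2
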