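"""Triangle subnetwork extraction, centralities, power method, meta-network."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from mirable.datatypes import PPINetwork, RegulatoryNetwork, Subnetwork
from mirable.subnetworks import (
    PowerMethodError,
    betweenness,
    build_analysis_graph,
    build_meta_network,
    closeness,
    eccentricity,
    extract_subnetwork,
    neighbours,
    power_method,
    triangle_partners,
)


def brute_force_subnetwork(graph: nx.DiGraph, seed) -> set:
    """O(n^3) oracle: enumerate all undirected triangles through the seed."""
    und = {frozenset(e) for e in graph.edges if e[0] != e[1]}

    def adj(a, b):
        return frozenset((a, b)) in und

    keep = set()
    for u, w in itertools.combinations(graph.nodes, 2):
        if u == seed or w == seed:
            continue
        if adj(seed, u) and adj(seed, w) and adj(u, w):
            keep.update((u, w))
    return {seed} | keep


def random_digraph(rng, n, p=0.25) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(str(i) for i in range(n))
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                g.add_edge(str(i), str(j))
    return g


class TestNeighbours:
    def test_isolated_node(self):
        g = nx.DiGraph()
        g.add_node("x")
        assert neighbours(g, "x") == frozenset()

    def test_toy_graph_reference_sets(self, toy_graph):
        assert neighbours(toy_graph, "1") == {"2", "4", "5"}
        assert neighbours(toy_graph, "2") - {"1"} == {"3", "4", "9", "11"}
        assert neighbours(toy_graph, "4") - {"1"} == {"2", "3", "6"}
        assert neighbours(toy_graph, "5") - {"1"} == {"6", "7", "8"}

    def test_matches_arc_scan_on_random_digraphs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = random_digraph(rng, 10)
            for v in g.nodes:
                expected = {
                    u
                    for u in g.nodes
                    if u != v and (g.has_edge(u, v) or g.has_edge(v, u))
                }
                assert neighbours(g, v) == expected


class TestExtractSubnetwork:
    def test_toy_graph_walkthrough(self, toy_graph):
        # reference intersections: N(1)&N(2)={4}, N(1)&N(4)={2}, N(1)&N(5)={}
        assert triangle_partners(toy_graph, "1", "2") == {"4"}
        assert triangle_partners(toy_graph, "1", "4") == {"2"}
        assert triangle_partners(toy_graph, "1", "5") == frozenset()
        sub = extract_subnetwork(toy_graph, "1")
        assert sub.nodes == {"1", "2", "4"}  # node 5 drops out

    def test_star_hub_is_singleton(self):
        g = nx.DiGraph()
        for leaf in "abcd":
            g.add_edge("hub", leaf)
        sub = extract_subnetwork(g, "hub")
        assert sub.nodes == {"hub"}

    def test_triangle_free_graph_all_singletons(self):
        g = nx.cycle_graph(6, create_using=nx.DiGraph)  # 6-cycle: no triangles
        g = nx.relabel_nodes(g, str)
        for v in g.nodes:
            assert extract_subnetwork(g, v).nodes == {v}

    def test_missing_seed_is_hard_error(self, toy_graph):
        with pytest.raises(KeyError):
            extract_subnetwork(toy_graph, "nope")

    def test_brute_force_oracle_random_digraphs(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = int(rng.integers(2, 13))
            g = random_digraph(rng, n)
            seed = str(rng.integers(0, n))
            sub = extract_subnetwork(g, seed)
            assert set(sub.nodes) == brute_force_subnetwork(g, seed)
            # arcs are induced: exactly the graph arcs among kept nodes
            expected_arcs = {
                (u, v) for u, v in g.edges if u in sub.nodes and v in sub.nodes
            }
            assert set(sub.graph.edges) == expected_arcs


class TestCentralities:
    def test_directed_cycle_uniform_betweenness(self):
        g = nx.DiGraph([("a", "b"), ("b", "c"), ("c", "a")])
        b = betweenness(g)
        assert max(b.values()) == pytest.approx(min(b.values()))

    def test_path_midpoint_has_max_betweenness(self):
        g = nx.DiGraph([("a", "b"), ("b", "c")])
        b = betweenness(g)
        assert b["b"] > b["a"] and b["b"] > b["c"]

    def test_closeness_and_eccentricity_on_disconnected(self):
        g = nx.DiGraph([("a", "b")])
        g.add_node("c")
        c = closeness(g)
        e = eccentricity(g)
        assert c["c"] == 0.0 and e["c"] == 0.0
        assert c["a"] == pytest.approx(0.5)  # reaches b at distance 1, of 2 others
        assert e["a"] == 1.0 and e["b"] == 0.0  # b is a sink

    def test_brute_force_shortest_path_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            g = random_digraph(rng, 10, p=0.3)
            n = g.number_of_nodes()
            # Floyd-Warshall by hand
            nodes = sorted(g.nodes)
            inf = float("inf")
            d = {(u, v): 0 if u == v else (1 if g.has_edge(u, v) else inf)
                 for u in nodes for v in nodes}
            for w in nodes:
                for u in nodes:
                    for v in nodes:
                        if d[u, w] + d[w, v] < d[u, v]:
                            d[u, v] = d[u, w] + d[w, v]
            c = closeness(g)
            e = eccentricity(g)
            for v in nodes:
                exp_c = sum(
                    1.0 / d[v, u] for u in nodes if u != v and d[v, u] < inf
                ) / (n - 1)
                reach = [d[v, u] for u in nodes if u != v and d[v, u] < inf]
                assert c[v] == pytest.approx(exp_c)
                assert e[v] == (max(reach) if reach else 0.0)


class TestPowerMethod:
    def test_complete_graph_uniform(self):
        g = nx.complete_graph(4, create_using=nx.DiGraph)
        g = nx.relabel_nodes(g, str)
        x, lam = power_method(g)
        assert all(v == pytest.approx(0.25, abs=1e-8) for v in x.values())
        assert lam == pytest.approx(3.0, abs=1e-6)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            power_method(nx.DiGraph())

    def test_nonconvergence_carries_last_iterate(self):
        # a path graph needs more than two sweeps to settle
        g = nx.DiGraph([("a", "b"), ("b", "a"), ("b", "c"), ("c", "b")])
        with pytest.raises(PowerMethodError) as err:
            power_method(g, tol=1e-12, max_iter=2)
        assert set(err.value.last) == {"a", "b", "c"}
        assert err.value.residual >= 0

    def test_bipartite_structure_still_converges(self):
        # a bare A-iteration oscillates on this star; the +I shift must not
        g = nx.DiGraph()
        for leaf in "bcde":
            g.add_edge("a", leaf)
            g.add_edge(leaf, "a")
        x, lam = power_method(g)
        assert lam == pytest.approx(2.0, abs=1e-6)  # sqrt(4) for the star
        assert sum(x.values()) == pytest.approx(1.0)

    def test_eigendecomposition_oracle_symmetric_graphs(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            n = int(rng.integers(2, 9))
            g = nx.DiGraph()
            nodes = [str(i) for i in range(n)]
            g.add_nodes_from(nodes)
            for i in range(1, n):  # spanning path keeps it connected
                g.add_edge(nodes[i - 1], nodes[i])
                g.add_edge(nodes[i], nodes[i - 1])
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        g.add_edge(nodes[i], nodes[j])
                        g.add_edge(nodes[j], nodes[i])
            x, lam = power_method(g)
            a = nx.to_numpy_array(g, nodelist=sorted(g.nodes, key=str))
            w, v = np.linalg.eigh(a)
            lead = v[:, np.argmax(w)]
            lead = np.abs(lead) / np.abs(lead).sum()
            got = np.array([x[k] for k in sorted(x, key=str)])
            assert np.abs(got - lead).sum() < 1e-6
            assert lam == pytest.approx(float(np.max(w)), abs=1e-6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(41)
        g = random_digraph(rng, 8, p=0.35)
        mapping = {v: f"z{v}" for v in g.nodes}
        h = nx.relabel_nodes(g, mapping)
        xg, _ = power_method(g)
        xh, _ = power_method(h)
        for v in g.nodes:
            assert xg[v] == pytest.approx(xh[mapping[v]], abs=1e-9)


class TestMetaNetwork:
    def _sub(self, seed, nodes):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        return Subnetwork(seed=seed, graph=g)

    def test_disjoint_subnetworks_no_arcs(self):
        meta = build_meta_network(
            [self._sub("a", ["a", "x"]), self._sub("b", ["b", "y"])]
        )
        assert meta.number_of_edges() == 0

    def test_one_way_membership_one_arc(self):
        meta = build_meta_network(
            [self._sub("a", ["a", "b", "x"]), self._sub("b", ["b", "y"])]
        )
        assert set(meta.edges) == {("a", "b")}

    def test_no_self_loops(self):
        meta = build_meta_network([self._sub("a", ["a"])])
        assert list(nx.selfloop_edges(meta)) == []

    def test_membership_matrix_oracle(self):
        rng = np.random.default_rng(53)
        universe = [f"n{i}" for i in range(12)]
        subs = []
        for i in range(10):
            seed = universe[i]
            members = {seed} | {
                u for u in universe if rng.random() < 0.3
            }
            subs.append(self._sub(seed, sorted(members)))
        meta = build_meta_network(subs)
        expected = {
            (a.seed, b.seed)
            for a in subs
            for b in subs
            if a.seed != b.seed and b.seed in a.nodes
        }
        assert set(meta.edges) == expected


def test_analysis_graph_structure():
    net = RegulatoryNetwork()
    net.add_edge("hsa-miR-1", "G1", -0.8, 1e-5, "literature")
    net.add_edge("hsa-miR-1", "G2", -0.7, 1e-4, "added")
    ppi = PPINetwork([("G1", "G2"), ("G1", "OUTSIDE")])
    g = build_analysis_graph(net, ppi)
    assert set(g.nodes) == {"hsa-miR-1", "G1", "G2"}
    assert g.has_edge("hsa-miR-1", "G1") and not g.has_edge("G1", "hsa-miR-1")
    assert g.has_edge("G1", "G2") and g.has_edge("G2", "G1")  # PPI both ways
    # the miRNA-shared PPI pair closes a triangle for every member
    assert extract_subnetwork(g, "G1").nodes == {"G1", "G2", "hsa-miR-1"}
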