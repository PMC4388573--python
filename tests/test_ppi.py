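"""PPI closure and the two-condition target-addition rule."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirable.datatypes import (
    BackgroundFunctions,
    EnrichmentResult,
    ExpressionMatrix,
    GOAnnotationMap,
    PPINetwork,
    PredictionTable,
    RegulatoryNetwork,
)
from mirable.ppi import add_targets, extend_network


def _bf(terms):
    return BackgroundFunctions(
        {t: EnrichmentResult(t, 1, 1, 1, 10, 0.01, 0.01) for t in terms}
    )


def _net_with_target(mirna="hsa-miR-1", target="T1"):
    net = RegulatoryNetwork(alpha=0.05, min_corr=0.3, n_samples=40)
    net.add_edge(mirna, target, -0.8, 1e-8, "literature")
    return net


def _expr(rows, n=None):
    cols = [f"s{i}" for i in range(len(next(iter(rows.values()))))]
    return ExpressionMatrix(pd.DataFrame(rows, index=cols).T)


class TestExtendNetwork:
    def test_no_touching_edges_imports_nothing(self):
        net = _net_with_target()
        ppi = PPINetwork([("A", "B")])
        ext = extend_network(net, ppi)
        assert ext.imported_genes == frozenset()

    def test_chain_depths(self):
        net = _net_with_target(target="t")
        ppi = PPINetwork([("t", "a"), ("a", "b"), ("b", "c")])
        ext = extend_network(net, ppi)
        assert ext.depth == {"a": 1, "b": 2, "c": 3}

    def test_max_depth_truncates(self):
        net = _net_with_target(target="t")
        ppi = PPINetwork([("t", "a"), ("a", "b"), ("b", "c")])
        ext = extend_network(net, ppi, max_depth=2)
        assert ext.depth == {"a": 1, "b": 2}

    def test_unlimited_closure_equals_connected_components(self):
        # oracle: union-find over the PPI edges; the closure must equal the
        # union of components containing a base target, minus the targets
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(50)]
        edges = [
            (genes[a], genes[b])
            for a, b in rng.integers(0, 50, size=(80, 2))
            if a != b
        ]
        ppi = PPINetwork(edges)
        net = _net_with_target(target="g0")
        net.add_edge("hsa-miR-2", "g7", -0.7, 1e-5, "literature")

        parent = {g: g for g in genes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in edges:
            if a != b:
                parent[find(a)] = find(b)
        roots = {find(t) for t in net.targets if t in parent}
        expected = {
            g for g in genes if find(g) in roots and g not in net.targets
        }
        ext = extend_network(net, ppi)
        assert set(ext.imported_genes) == expected


class TestAddTargets:
    def _setup(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal(40)
        anti = -0.8 * z + 0.6 * rng.standard_normal(40)
        net = _net_with_target(mirna="hsa-miR-1", target="T1")
        ppi = PPINetwork([("T1", "CAND"), ("CAND", "DEEP")])
        mrna = _expr({
            "T1": -0.8 * z + 0.6 * rng.standard_normal(40),
            "CAND": anti,
            "DEEP": -0.8 * z + 0.6 * rng.standard_normal(40),
        })
        mirna_m = _expr({"hsa-miR-1": z})
        ann = GOAnnotationMap(
            [("CAND", "GO:1"), ("DEEP", "GO:1"), ("T1", "GO:1")]
        )
        return net, ppi, mrna, mirna_m, ann

    def test_candidate_without_network_mirna_rejected(self):
        net, ppi, mrna, mirna_m, ann = self._setup()
        ext = extend_network(net, ppi)
        preds = PredictionTable([("hsa-miR-99", "CAND")])  # not in network
        out = add_targets(ext, _bf(["GO:1"]), ann, preds, mrna, mirna_m)
        assert "CAND" not in out.targets

    def test_candidate_without_background_term_rejected(self):
        net, ppi, mrna, mirna_m, ann = self._setup()
        ext = extend_network(net, ppi)
        preds = PredictionTable([("hsa-miR-1", "CAND")])
        out = add_targets(ext, _bf(["GO:OTHER"]), ann, preds, mrna, mirna_m)
        assert "CAND" not in out.targets

    def test_qualifying_candidate_admitted_with_edges_to_M(self):
        net, ppi, mrna, mirna_m, ann = self._setup()
        ext = extend_network(net, ppi)
        preds = PredictionTable([("hsa-miR-1", "CAND"), ("hsa-miR-1", "DEEP")])
        out = add_targets(ext, _bf(["GO:1"]), ann, preds, mrna, mirna_m)
        assert ("hsa-miR-1", "CAND") in out
        assert out.origin["CAND"] == "added"
        assert out.edges[("hsa-miR-1", "CAND")].p_value <= 0.01
        # same qualifications at depth 2: never considered
        assert "DEEP" not in out.targets

    def test_base_network_is_subgraph_of_output(self):
        net, ppi, mrna, mirna_m, ann = self._setup()
        ext = extend_network(net, ppi)
        preds = PredictionTable([("hsa-miR-1", "CAND")])
        out = add_targets(ext, _bf(["GO:1"]), ann, preds, mrna, mirna_m)
        assert set(net.edges) <= set(out.edges)
        for key in net.edges:
            assert out.edges[key] == net.edges[key]

    def test_second_invocation_guarded(self):
        net, ppi, mrna, mirna_m, ann = self._setup()
        preds = PredictionTable([("hsa-miR-1", "CAND")])
        out = add_targets(
            extend_network(net, ppi), _bf(["GO:1"]), ann, preds, mrna, mirna_m
        )
        with pytest.raises(RuntimeError, match="once"):
            add_targets(
                extend_network(out, ppi), _bf(["GO:1"]), ann, preds, mrna,
                mirna_m,
            )

    def test_fixture_planted_interactors(self, fixture_inputs):
        from mirable.enrichment import background_functions
        from mirable.regnet import build_regulatory_network

        man = fixture_inputs["manifest"]
        net = build_regulatory_network(
            set(man["disease_genes"]), fixture_inputs["preds"],
            fixture_inputs["mrna"], fixture_inputs["mirna"],
        )
        bf = background_functions(man["disease_genes"], fixture_inputs["ann"])
        ext = extend_network(net, fixture_inputs["ppi"])
        out = add_targets(
            ext, bf, fixture_inputs["ann"], fixture_inputs["preds"],
            fixture_inputs["mrna"], fixture_inputs["mirna"],
        )
        ints = man["interactors"]
        for g in ints["admissible_depth1"]:
            assert ext.depth[g] == 1
            assert g in out.targets and out.origin[g] == "added"
        assert ext.depth[ints["depth2"]] == 2
        assert ints["depth2"] not in out.targets
        assert ints["no_term_depth1"] not in out.targets
        assert ints["no_prediction_depth1"] not in out.targets
        # audit: every added edge re-verifies conditions (a) and (b)
        from mirable.regnet import pearson

        for (m, t), e in out.edges.items():
            if e.origin != "added":
                continue
            assert (m, t) in fixture_inputs["preds"] and m in net.mirnas
            r = pearson(
                fixture_inputs["mrna"].vector(t),
                fixture_inputs["mirna"].vector(m),
            )
            assert r.rho < 0 and r.p_value <= 0.01
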