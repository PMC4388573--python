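"""Triangle subnetwork extraction, centrality indices and the meta-network.

The analysis graph contains the regulatory part of the extended network:
miRNAs and their direct targets, with directed miRNA -> target arcs and
PPI interactions between in-network genes as arc pairs in both directions.

For each seed node v the regulatory subnetwork keeps, besides v itself,
exactly the neighbours u of v for which the seed's neighbourhood
intersects N(u) \\ {v} - that is, the neighbours closing at least one
triangle with the seed.  Arcs are induced from the analysis graph.
Triangles are found on the undirected view of the arcs; centralities use
the directed arcs.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .datatypes import (
    PPINetwork,
    RegulatoryNetwork,
    Subnetwork,
    is_mirna,
)

logger = logging.getLogger(__name__)


def build_analysis_graph(net: RegulatoryNetwork, ppi: PPINetwork) -> nx.DiGraph:
    """Directed graph over the network's miRNAs and direct targets.

    miRNA -> target arcs carry the regulatory direction; every PPI edge
    whose two endpoints are both in-network targets contributes arcs in
    both directions.
    """
    g = nx.DiGraph()
    for m in sorted(net.mirnas):
        g.add_node(m, kind="mirna")
    for t in sorted(net.targets):
        g.add_node(t, kind="gene")
    for (m, t) in sorted(net.edges):
        g.add_edge(m, t, kind="targets")
    targets = net.targets
    for a, b in sorted(ppi.edges):
        if a in targets and b in targets:
            g.add_edge(a, b, kind="interacts")
            g.add_edge(b, a, kind="interacts")
    return g


def neighbours(graph: nx.DiGraph, node: str) -> frozenset[str]:
    """Undirected neighbourhood: union of in- and out-neighbours, minus self."""
    if node not in graph:
        raise KeyError(f"node {node!r} not in graph")
    both = frozenset(graph.successors(node)) | frozenset(graph.predecessors(node))
    return both - {node}


def triangle_partners(graph: nx.DiGraph, seed: str, u: str) -> frozenset[str]:
    """Nodes completing a triangle through seed and its neighbour u.

    The intersection N(seed) & (N(u) \\ {seed}) from the subnetwork
    construction; nonempty iff u closes a triangle with the seed.
    """
    return neighbours(graph, seed) & (neighbours(graph, u) - {seed})


def extract_subnetwork(graph: nx.DiGraph, seed: str) -> Subnetwork:
    """Triangle-closure subnetwork of *seed* with induced arcs.

    Neighbours that close no triangle with the seed are excluded; a seed
    with no triangles yields the singleton subnetwork {seed}.
    """
    if seed not in graph:
        raise KeyError(f"seed {seed!r} not in graph")
    nbrs = neighbours(graph, seed)
    keep = {u for u in nbrs if triangle_partners(graph, seed, u)}
    nodes = {seed} | keep
    sub = nx.DiGraph(graph.subgraph(nodes).copy())
    return Subnetwork(seed=seed, graph=sub)


def extract_all_subnetworks(graph: nx.DiGraph) -> dict[str, Subnetwork]:
    """One subnetwork per node of the analysis graph, keyed by seed."""
    return {v: extract_subnetwork(graph, v) for v in sorted(graph.nodes)}


# ---------------------------------------------------------------------------
# Centrality indices

def betweenness(graph: nx.DiGraph) -> dict[str, float]:
    """Directed shortest-path betweenness centrality (normalised)."""
    return {
        str(v): float(c)
        for v, c in nx.betweenness_centrality(graph, normalized=True).items()
    }


def closeness(graph: nx.DiGraph) -> dict[str, float]:
    """Directed closeness in the harmonic convention.

    closeness(v) = (1/(n-1)) * sum over u != v reachable from v of 1/d(v, u);
    an unreachable pair contributes 0, so the index is defined on
    disconnected graphs.
    """
    n = graph.number_of_nodes()
    out: dict[str, float] = {}
    for v in graph.nodes:
        dists = nx.single_source_shortest_path_length(graph, v)
        total = sum(1.0 / d for u, d in dists.items() if u != v and d > 0)
        out[str(v)] = total / (n - 1) if n > 1 else 0.0
    return out


def eccentricity(graph: nx.DiGraph) -> dict[str, float]:
    """Directed eccentricity over each node's reachable set (0 for sinks)."""
    out: dict[str, float] = {}
    for v in graph.nodes:
        dists = nx.single_source_shortest_path_length(graph, v)
        reach = [d for u, d in dists.items() if u != v]
        out[str(v)] = float(max(reach)) if reach else 0.0
    return out


class PowerMethodError(RuntimeError):
    """Power iteration failed to converge; carries the last iterate."""

    def __init__(self, message: str, last: Mapping[str, float], residual: float):
        super().__init__(message)
        self.last = dict(last)
        self.residual = residual


def power_method(
    graph: nx.DiGraph,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> tuple[dict[str, float], float]:
    """Eigenvector centrality by power iteration on the adjacency matrix.

    Solves lambda x = A x for the dominant eigenpair by iterating
    x <- (A + I) x / ||(A + I) x||_1 from the uniform vector.  The identity
    shift leaves the eigenvectors of A unchanged while suppressing the
    oscillation a bare iteration exhibits on bipartite or periodic
    structures.  Returns the L1-normalised non-negative vector and the
    Rayleigh estimate of lambda for A itself.
    """
    nodes: Sequence[str] = sorted(graph.nodes, key=str)
    if not nodes:
        raise ValueError("power method undefined on an empty graph")
    a = nx.to_numpy_array(graph, nodelist=nodes, dtype=float)
    n = len(nodes)
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        y = a @ x + x  # (A + I) x
        norm = np.abs(y).sum()
        if norm == 0.0:  # unreachable with the +I shift, kept as a guard
            raise PowerMethodError(
                "iteration collapsed to the zero vector",
                dict(zip(nodes, x)), float("inf"),
            )
        y /= norm
        delta = np.abs(y - x).sum()
        x = y
        if delta < tol:
            ax = a @ x
            lam = float(x @ ax / (x @ x))
            return dict(zip(nodes, (float(v) for v in x))), lam
    raise PowerMethodError(
        f"power method did not converge in {max_iter} iterations",
        dict(zip(nodes, x)), float(delta),
    )


def centrality_table(
    graph: nx.DiGraph, tol: float = 1e-10, max_iter: int = 100_000
) -> dict[str, dict[str, float]]:
    """All four centrality indices, keyed by index name then node."""
    power, _lam = power_method(graph, tol=tol, max_iter=max_iter)
    return {
        "betweenness": betweenness(graph),
        "closeness": closeness(graph),
        "eccentricity": eccentricity(graph),
        "power": power,
    }


# ---------------------------------------------------------------------------
# Meta-network

def build_meta_network(subnets: Iterable[Subnetwork]) -> nx.DiGraph:
    """Directed meta-network over subnetworks (nodes keyed by seed).

    Arc A -> B exists iff the seed of B belongs to the node set of A and
    A != B; trivial self-membership of a seed in its own subnetwork never
    creates a self-loop.
    """
    subnet_list = list(subnets)
    g = nx.DiGraph()
    for s in subnet_list:
        g.add_node(s.seed)
    for a in subnet_list:
        for b in subnet_list:
            if a.seed != b.seed and b.seed in a.nodes:
                g.add_edge(a.seed, b.seed)
    return g
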