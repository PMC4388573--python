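"""PPI-driven network extension and guilt-by-association target addition.

The regulatory network's targets all come from the literature; to surface
genes never or poorly studied with the disease, the network is first
closed over the protein-protein interaction graph (breadth-first from the
target set), then direct interactors of targets are admitted as new
targets when they carry a disease background function, are predicted
targets of a network miRNA, and are strongly anticorrelated with at least
one such miRNA.  The addition runs exactly once: recursing would chain
weak links into the network.
"""

from __future__ import annotations

import logging
from collections import deque

from .datatypes import (
    BackgroundFunctions,
    ExpressionMatrix,
    ExtendedNetwork,
    GOAnnotationMap,
    PPINetwork,
    PredictionTable,
    RegulatoryNetwork,
)
from .regnet import _check_same_samples, pearson

logger = logging.getLogger(__name__)


def extend_network(
    net: RegulatoryNetwork,
    ppi: PPINetwork,
    max_depth: int | None = None,
) -> ExtendedNetwork:
    """Breadth-first PPI closure from the network's target set.

    Base targets sit at depth 0 (not recorded); each imported gene records
    its BFS depth.  ``max_depth=None`` imports until no more interactors can
    be reached, i.e. the union of PPI connected components touching the
    targets.
    """
    depth: dict[str, int] = {}
    visited: set[str] = set(net.targets)
    queue: deque[tuple[str, int]] = deque((t, 0) for t in sorted(net.targets))
    while queue:
        gene, d = queue.popleft()
        if max_depth is not None and d >= max_depth:
            continue
        for nb in sorted(ppi.neighbors(gene)):
            if nb in visited:
                continue
            visited.add(nb)
            depth[nb] = d + 1
            queue.append((nb, d + 1))
    used = frozenset(
        e for e in ppi.edges if e[0] in visited and e[1] in visited
    )
    logger.info(
        "extend_network: imported %d gene(s) from %d base target(s) "
        "(max_depth=%s, %d PPI edges inside the closure)",
        len(depth), len(net.targets), max_depth, len(used),
    )
    return ExtendedNetwork(base=net, depth=depth, ppi_edges_used=used)


def add_targets(
    ext: ExtendedNetwork,
    bf: BackgroundFunctions,
    ann: GOAnnotationMap,
    preds: PredictionTable,
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    alpha_add: float = 0.01,
) -> RegulatoryNetwork:
    """Admit qualifying direct interactors of targets as new network targets.

    Candidates are the imported genes at PPI depth exactly 1 that carry at
    least one background function.  A candidate is accepted iff (a) it is a
    predicted target of at least one network miRNA and (b) it is negatively
    correlated with at least one miRNA from (a) at p <= *alpha_add*; it is
    then connected to every miRNA of its qualifying set M.  Deeper imports
    are never candidates, and the procedure refuses to run twice.
    """
    net = ext.base
    if net.extended:
        raise RuntimeError(
            "target addition already applied to this network; the procedure "
            "runs exactly once"
        )
    _check_same_samples(mrna, mirna)
    out = net.copy()
    out.extended = True

    candidates = sorted(
        g
        for g, d in ext.depth.items()
        if d == 1 and (ann.terms_for(g) & bf.terms)
    )
    n_admitted = 0
    for gene in candidates:
        if gene not in mrna:
            continue
        predicted = preds.mirnas_for(gene) & net.mirnas  # condition (a)
        if not predicted:
            continue
        gx = mrna.vector(gene)
        qualifying = []
        for m in sorted(predicted):
            if m not in mirna:
                continue
            corr = pearson(gx, mirna.vector(m))
            if corr.ok and corr.rho < 0.0 and corr.p_value <= alpha_add:
                qualifying.append((m, corr))  # condition (b)
        if not qualifying:
            continue
        for m, corr in qualifying:
            out.add_edge(m, gene, corr.rho, corr.p_value, origin="added")
        n_admitted += 1
    logger.info(
        "add_targets: %d candidate(s) at depth 1 with a background function, "
        "%d admitted (alpha_add=%g)",
        len(candidates), n_admitted, alpha_add,
    )
    return out
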