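"""Shared in-memory containers for the pipeline stages.

Node identifiers live in two disjoint namespaces: miRNA names (recognised
by prefix, e.g. ``hsa-miR-494``) and gene identifiers (symbols or numeric
NCBI-style IDs).  A node is one or the other, never both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd

#: Prefixes that mark an identifier as a miRNA rather than a gene.
MIRNA_PREFIXES: tuple[str, ...] = ("hsa-miR", "hsa-let")


def is_mirna(name: str, prefixes: Iterable[str] = MIRNA_PREFIXES) -> bool:
    """True if *name* belongs to the miRNA namespace (prefix match)."""
    return any(name.startswith(p) for p in prefixes)


class ExpressionMatrix:
    """Normalised expression values, features (rows) x samples (columns).

    Thin validation wrapper around a :class:`pandas.DataFrame`.  Requires at
    least three samples (a Pearson correlation p-value is undefined below
    that), unique feature identifiers and finite values throughout.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[1] < 3:
            raise ValueError(
                f"expression matrix needs >= 3 samples, got {data.shape[1]}"
            )
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature identifiers: {dups}")
        values = data.to_numpy(dtype=float)  # raises on non-numeric cells
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")
        self.data = data.astype(float)

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def vector(self, feature: str) -> np.ndarray:
        return self.data.loc[feature].to_numpy(dtype=float)

    def __contains__(self, feature: str) -> bool:
        return feature in self.data.index

    def __repr__(self) -> str:
        return (
            f"ExpressionMatrix({self.data.shape[0]} features x "
            f"{self.data.shape[1]} samples)"
        )


class PredictionTable:
    """Set of predicted (miRNA, target gene) pairs with set semantics.

    ``mirnas_for(t)`` realises the prediction lookup P(t): the set of miRNAs
    predicted to target gene ``t`` (empty for unseen genes).
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.pairs: frozenset[tuple[str, str]] = frozenset(
            (str(m), str(t)) for m, t in pairs
        )
        by_target: dict[str, set[str]] = {}
        by_mirna: dict[str, set[str]] = {}
        for m, t in self.pairs:
            by_target.setdefault(t, set()).add(m)
            by_mirna.setdefault(m, set()).add(t)
        self._by_target = {t: frozenset(s) for t, s in by_target.items()}
        self._by_mirna = {m: frozenset(s) for m, s in by_mirna.items()}

    def mirnas_for(self, target: str) -> frozenset[str]:
        return self._by_target.get(target, frozenset())

    def targets_for(self, mirna: str) -> frozenset[str]:
        return self._by_mirna.get(mirna, frozenset())

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(self._by_mirna)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._by_target)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


class PPINetwork:
    """Undirected protein-protein interaction edges (no self-loops).

    Self-loops in the input are dropped and counted in
    :attr:`n_self_loops_dropped`; duplicate and reversed pairs collapse.
    """

    def __init__(self, edges: Iterable[tuple[str, str]]):
        seen: set[tuple[str, str]] = set()
        dropped = 0
        adj: dict[str, set[str]] = {}
        for a, b in edges:
            a, b = str(a), str(b)
            if a == b:
                dropped += 1
                continue
            key = (a, b) if a < b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        self.edges: frozenset[tuple[str, str]] = frozenset(seen)
        self._adj = {g: frozenset(s) for g, s in adj.items()}
        self.n_self_loops_dropped = dropped

    def neighbors(self, gene: str) -> frozenset[str]:
        return self._adj.get(gene, frozenset())

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self._adj)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return ((a, b) if a < b else (b, a)) in self.edges

    def __len__(self) -> int:
        return len(self.edges)


class GOAnnotationMap:
    """Gene -> GO-term annotations with the exact inverse map maintained."""

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        g2t: dict[str, set[str]] = {}
        t2g: dict[str, set[str]] = {}
        for gene, term in pairs:
            gene, term = str(gene), str(term)
            g2t.setdefault(gene, set()).add(term)
            t2g.setdefault(term, set()).add(gene)
        self.gene_to_terms = {g: frozenset(s) for g, s in g2t.items()}
        self.term_to_genes = {t: frozenset(s) for t, s in t2g.items()}

    def terms_for(self, gene: str) -> frozenset[str]:
        return self.gene_to_terms.get(gene, frozenset())

    def genes_for(self, term: str) -> frozenset[str]:
        return self.term_to_genes.get(term, frozenset())

    @property
    def universe(self) -> frozenset[str]:
        """All annotated genes (the enrichment universe G_GO)."""
        return frozenset(self.gene_to_terms)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.term_to_genes)

    def __len__(self) -> int:
        return sum(len(s) for s in self.gene_to_terms.values())


@dataclass(frozen=True)
class LiteratureCounts:
    """Publication counts behind one gene's disease score.

    m: articles with human gene information; n: those also disease-related;
    j: articles about this gene; k: articles about this gene AND the disease.
    """

    m: int
    n: int
    j: int
    k: int

    def __post_init__(self):
        if min(self.m, self.n, self.j, self.k) < 0:
            raise ValueError("negative publication count")
        if self.n > self.m or self.j > self.m:
            raise ValueError(f"need n <= m and j <= m, got {self}")
        if self.k > min(self.n, self.j):
            raise ValueError(f"need k <= min(n, j), got {self}")


@dataclass(frozen=True)
class DiseaseScoreRecord:
    """One gene's literature disease score (ds = -log10 of the tail prob)."""

    gene: str
    counts: LiteratureCounts
    H: float
    ds: float

    @property
    def n_pubs(self) -> int:
        """Number of supporting disease publications (the overlap k)."""
        return self.counts.k


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-sided t-test p-value.

    ``ok`` is False when the correlation is undefined (zero variance); such
    pairs always fail the anticorrelation filter.
    """

    rho: float
    n_samples: int
    p_value: float
    ok: bool = True
    reason: str | None = None


@dataclass(frozen=True)
class RegEdge:
    """One retained miRNA -> target edge with its correlation evidence."""

    mirna: str
    gene: str
    rho: float
    p_value: float
    origin: str  # "literature" (base RC edge) or "added" (target addition)


class RegulatoryNetwork:
    """Bipartite miRNA -> target network annotated with correlations.

    ``origin`` tags each target as coming from the literature-seeded RC set
    or from the PPI-driven target-addition step.  ``extended`` flips once
    target addition has run; the procedure is single-shot by design.
    """

    def __init__(
        self,
        *,
        alpha: float | None = None,
        min_corr: float | None = None,
        n_samples: int | None = None,
    ):
        self.edges: dict[tuple[str, str], RegEdge] = {}
        self.mirnas: set[str] = set()
        self.targets: set[str] = set()
        self.origin: dict[str, str] = {}
        self.alpha = alpha
        self.min_corr = min_corr
        self.n_samples = n_samples
        self.extended = False

    def add_edge(
        self, mirna: str, gene: str, rho: float, p_value: float,
        origin: str = "literature",
    ) -> None:
        if origin not in ("literature", "added"):
            raise ValueError(f"unknown edge origin {origin!r}")
        self.edges[(mirna, gene)] = RegEdge(mirna, gene, rho, p_value, origin)
        self.mirnas.add(mirna)
        self.targets.add(gene)
        # a target admitted later never demotes a literature tag
        if self.origin.get(gene) != "literature":
            self.origin[gene] = origin

    def copy(self) -> "RegulatoryNetwork":
        new = RegulatoryNetwork(
            alpha=self.alpha, min_corr=self.min_corr, n_samples=self.n_samples
        )
        new.edges = dict(self.edges)
        new.mirnas = set(self.mirnas)
        new.targets = set(self.targets)
        new.origin = dict(self.origin)
        new.extended = self.extended
        return new

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.edges


@dataclass
class ExtendedNetwork:
    """Regulatory network plus the PPI import closure around its targets.

    ``depth`` maps each imported gene to its BFS distance from the nearest
    base target (1 = direct interactor); base targets themselves are depth 0
    and not listed.
    """

    base: RegulatoryNetwork
    depth: dict[str, int]
    ppi_edges_used: frozenset[tuple[str, str]]

    @property
    def imported_genes(self) -> frozenset[str]:
        return frozenset(self.depth)


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term enrichment counts and p-values (raw and BH-adjusted)."""

    term: str
    k: int
    j: int
    n: int
    m: int
    p_raw: float
    p_adj: float


class BackgroundFunctions:
    """Disease background function set: GO terms with BH-adjusted p <= alpha."""

    def __init__(self, results: Mapping[str, EnrichmentResult]):
        self.results = dict(results)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.results)

    def __contains__(self, term: str) -> bool:
        return term in self.results

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.results))

    def __len__(self) -> int:
        return len(self.results)


@dataclass
class Subnetwork:
    """Triangle-closure ego subnetwork of one seed node.

    Nodes are the seed plus every neighbour closing at least one triangle
    with it; arcs are the induced directed arcs of the analysis graph.
    """

    seed: str
    graph: nx.DiGraph

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def gene_nodes(self) -> frozenset[str]:
        return frozenset(v for v in self.graph.nodes if not is_mirna(v))


@dataclass(frozen=True)
class RankRecord:
    """One row of the final ranking report.

    rs: regulatory subnetwork score S(v); ds: the seed's literature disease
    score, with -1.00 standing in for miRNA seeds and for genes with fewer
    than the reporting minimum of supporting disease publications; pm: the
    seed's meta-network power-method score.
    """

    seed: str
    nr_nodes: int
    rs: float
    ds: float
    pm: float
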