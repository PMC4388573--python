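from __future__ import annotations

import networkx as nx
import pytest

from mirable import io as mio
from mirable.synth import FixtureSpec, generate

#: reference neighbourhood facts of the toy network used in the subnetwork
#: construction walkthrough: node 1 adjacent to 2, 4, 5; the seed-excluded
#: neighbourhoods N(2)={3,4,9,11}, N(4)={2,3,6}, N(5)={6,7,8}
TOY_ADJACENCY = {
    1: {2, 4, 5},
    2: {3, 4, 9, 11},
    4: {2, 3, 6},
    5: {6, 7, 8},
}


def make_toy_graph() -> nx.DiGraph:
    """Toy analysis graph from the reference adjacency facts (undirected view)."""
    g = nx.DiGraph()
    for u, nbrs in TOY_ADJACENCY.items():
        for v in nbrs:
            g.add_edge(str(u), str(v))
            g.add_edge(str(v), str(u))
    return g


@pytest.fixture(scope="session")
def toy_graph() -> nx.DiGraph:
    return make_toy_graph()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Default-condition synthetic dataset, generated once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    manifest = generate(FixtureSpec(rng_seed=7), out)
    return manifest


@pytest.fixture(scope="session")
def fixture_inputs(fixture_dir):
    """The five fixture inputs loaded through the package readers."""
    paths = fixture_dir["paths"]
    return {
        "gene_pubs": mio.read_gene2pubmed(paths["gene2pubmed"], taxon="9606"),
        "disease_pmids": mio.read_pmid_list(paths["disease_pmids"]),
        "preds": mio.read_predictions(paths["predictions"]),
        "mrna": mio.read_expression(paths["mrna"]),
        "mirna": mio.read_expression(paths["mirna"]),
        "ppi": mio.read_ppi(paths["ppi"]),
        "ann": mio.read_go_annotations(paths["go"]),
        "manifest": fixture_dir,
    }
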