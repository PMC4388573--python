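"""End-to-end orchestration of the three-step method.

Stages communicate via plain-text artifacts in the output directory, so
any stage can be inspected or re-run in isolation:

1. literature scoring  ->  literature.csv (all genes) + the selected set
2. network building    ->  edges.tsv; background selection -> background.csv
   PPI extension + target addition -> edges_extended.tsv
3. subnetwork extraction (one SIF per seed), centralities.csv,
   meta-network power method, ranking.csv

The pipeline uses no randomness: identical inputs give byte-identical
artifacts, and a SHA-256 of every artifact is recorded in the run log.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as mio
from .datatypes import DiseaseScoreRecord, LiteratureCounts
from .enrichment import background_functions
from .literature import score_genes
from .ppi import add_targets, extend_network
from .ranking import rank_seeds, score_all_subnetworks
from .regnet import build_regulatory_network
from .subnetworks import (
    build_analysis_graph,
    build_meta_network,
    centrality_table,
    extract_all_subnetworks,
    power_method,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and thresholds for a full run."""

    gene2pubmed: str
    disease_pmids: str
    predictions: str
    mrna: str
    mirna: str
    ppi: str
    go: str
    out_dir: str
    taxon: str = "9606"
    ds_threshold: float = 4.0
    alpha_corr: float = 0.05
    alpha_add: float = 0.01
    alpha_bf: float = 0.05
    enrichment_mode: str = "paper"
    power_tol: float = 1e-10
    power_max_iter: int = 100_000
    dedup: str = "error"
    max_ppi_depth: int | None = None
    write_sifs: bool = True

    def __post_init__(self):
        for name in ("alpha_corr", "alpha_add", "alpha_bf"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.ds_threshold < 0:
            raise ValueError("ds_threshold must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_literature_csv(records: dict[str, DiseaseScoreRecord], path: Path):
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["gene", "m", "n", "j", "k", "H", "ds"])
        for g in sorted(records):
            r = records[g]
            c = r.counts
            w.writerow([g, c.m, c.n, c.j, c.k, f"{r.H:.10g}", f"{r.ds:.10g}"])


def read_literature_csv(path: str | Path) -> dict[str, DiseaseScoreRecord]:
    records: dict[str, DiseaseScoreRecord] = {}
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            counts = LiteratureCounts(
                m=int(row["m"]), n=int(row["n"]), j=int(row["j"]), k=int(row["k"])
            )
            records[row["gene"]] = DiseaseScoreRecord(
                gene=row["gene"], counts=counts,
                H=float(row["H"]), ds=float(row["ds"]),
            )
    return records


def _write_background_csv(bf, path: Path):
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["term", "k", "j", "n", "m", "p_raw", "p_adj"])
        for term in bf:
            r = bf.results[term]
            w.writerow(
                [term, r.k, r.j, r.n, r.m, f"{r.p_raw:.10g}", f"{r.p_adj:.10g}"]
            )


def _write_centralities_csv(table: dict[str, dict[str, float]], path: Path):
    nodes = sorted(table["power"])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node", "betweenness", "closeness", "eccentricity", "power"])
        for v in nodes:
            w.writerow(
                [v]
                + [f"{table[idx][v]:.10g}"
                   for idx in ("betweenness", "closeness", "eccentricity", "power")]
            )


def run(config: PipelineConfig) -> dict[str, Path]:
    """Execute all three steps; returns the artifact paths.

    The run log (``run_log.txt``) records every threshold, the
    before/after count of each filter, and a SHA-256 of each artifact.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def note(msg: str):
        logger.info(msg)
        log_lines.append(msg)

    # ---- load inputs ------------------------------------------------------
    gene_pubs = mio.read_gene2pubmed(config.gene2pubmed, taxon=config.taxon)
    disease_pmids = mio.read_pmid_list(config.disease_pmids)
    preds = mio.read_predictions(config.predictions)
    mrna = mio.read_expression(config.mrna, dedup=config.dedup)
    mirna = mio.read_expression(config.mirna, dedup=config.dedup)
    ppi = mio.read_ppi(config.ppi)
    ann = mio.read_go_annotations(config.go)
    note(
        f"inputs: {len(gene_pubs)} genes with publications, "
        f"{len(disease_pmids)} disease publications, {len(preds)} predicted "
        f"pairs, {len(ppi)} PPI edges, {len(ann.universe)} annotated genes"
    )

    # ---- step 1: literature scoring + base network ------------------------
    lit_records = score_genes(gene_pubs, disease_pmids)
    selected = {
        g: r for g, r in lit_records.items() if r.ds > config.ds_threshold
    }
    note(
        f"literature: {len(gene_pubs)} scored genes -> {len(selected)} with "
        f"ds > {config.ds_threshold}"
    )
    literature_csv = out / "literature.csv"
    _write_literature_csv(lit_records, literature_csv)

    net = build_regulatory_network(
        selected, preds, mrna, mirna, alpha=config.alpha_corr
    )
    note(
        f"base network: {len(net)} edges over {len(net.mirnas)} miRNAs and "
        f"{len(net.targets)} targets (min_corr={net.min_corr:.4f} at "
        f"alpha={config.alpha_corr}, n={net.n_samples})"
    )
    edges_tsv = out / "edges.tsv"
    mio.write_network_tsv(net, edges_tsv)

    # ---- step 2: background functions + PPI extension ---------------------
    bf = background_functions(
        selected, ann, alpha=config.alpha_bf, mode=config.enrichment_mode
    )
    note(
        f"background functions: {len(bf)} terms at BH-adjusted "
        f"p <= {config.alpha_bf} (mode={config.enrichment_mode})"
    )
    background_csv = out / "background.csv"
    _write_background_csv(bf, background_csv)

    ext = extend_network(net, ppi, max_depth=config.max_ppi_depth)
    note(
        f"PPI extension: {len(ext.imported_genes)} imported genes "
        f"({sum(1 for d in ext.depth.values() if d == 1)} at depth 1)"
    )
    extended = add_targets(
        ext, bf, ann, preds, mrna, mirna, alpha_add=config.alpha_add
    )
    n_added = sum(1 for t, o in extended.origin.items() if o == "added")
    note(
        f"target addition: {n_added} new targets, "
        f"{len(extended) - len(net)} new edges (p <= {config.alpha_add})"
    )
    edges_ext_tsv = out / "edges_extended.tsv"
    mio.write_network_tsv(extended, edges_ext_tsv)

    # ---- step 3: subnetworks, centralities, ranking -----------------------
    graph = build_analysis_graph(extended, ppi)
    subnets = extract_all_subnetworks(graph)
    note(
        f"analysis graph: {graph.number_of_nodes()} nodes, "
        f"{graph.number_of_edges()} arcs; {len(subnets)} subnetworks"
    )
    artifacts: dict[str, Path] = {
        "literature": literature_csv,
        "edges": edges_tsv,
        "background": background_csv,
        "edges_extended": edges_ext_tsv,
    }
    if config.write_sifs and subnets:
        sif_dir = out / "subnetworks"
        sif_dir.mkdir(exist_ok=True)
        for seed, sub in sorted(subnets.items()):
            mio.write_subnetwork_sif(sub, sif_dir / f"{seed}.sif")
        artifacts["subnetworks_dir"] = sif_dir

    if graph.number_of_nodes() > 0:
        table = centrality_table(
            graph, tol=config.power_tol, max_iter=config.power_max_iter
        )
        centralities_csv = out / "centralities.csv"
        _write_centralities_csv(table, centralities_csv)
        artifacts["centralities"] = centralities_csv

        meta = build_meta_network(subnets.values())
        meta_pm, lam = power_method(
            meta, tol=config.power_tol, max_iter=config.power_max_iter
        )
        note(
            f"meta-network: {meta.number_of_nodes()} nodes, "
            f"{meta.number_of_edges()} arcs, dominant eigenvalue {lam:.4f}"
        )
        scores = score_all_subnetworks(
            subnets, bf, ann, mode=config.enrichment_mode
        )
        records = rank_seeds(subnets, scores, meta_pm, lit_records)
    else:
        note("analysis graph is empty; ranking is empty")
        records = []
    ranking_csv = out / "ranking.csv"
    mio.write_ranking_csv(records, ranking_csv)
    artifacts["ranking"] = ranking_csv

    # ---- run log with artifact hashes -------------------------------------
    for name in sorted(artifacts):
        p = artifacts[name]
        if p.is_dir():
            for sif in sorted(p.iterdir()):
                log_lines.append(f"artifact {name}/{sif.name} sha256={_sha256(sif)}")
        else:
            log_lines.append(f"artifact {name} sha256={_sha256(p)}")
    run_log = out / "run_log.txt"
    run_log.write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    artifacts["run_log"] = run_log
    return artifacts
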