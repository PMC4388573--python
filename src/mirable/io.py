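"""Readers and writers for the external file formats.

All text I/O is UTF-8, tab-delimited; lines starting with ``#`` are
comments and blank lines are skipped.  Readers de-duplicate into set
semantics so the in-memory structures are independent of input row order.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterator

import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GOAnnotationMap,
    PPINetwork,
    PredictionTable,
    RankRecord,
    RegulatoryNetwork,
    Subnetwork,
    is_mirna,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file (wrong column count, bad value, ...)."""


def _rows(path: str | Path, n_cols: int | None = None) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for data lines of a TSV file."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if n_cols is not None and len(fields) < n_cols:
                raise FormatError(
                    f"{path}: line {lineno}: expected {n_cols} tab-separated "
                    f"columns, got {len(fields)}"
                )
            yield lineno, fields


def read_gene2pubmed(path: str | Path, taxon: str) -> dict[str, set[str]]:
    """Read a gene2pubmed-style TSV (tax_id, gene, publication).

    Only rows whose first column equals *taxon* are retained; the result
    maps each gene to its set of distinct publication IDs.
    """
    out: dict[str, set[str]] = {}
    for _lineno, fields in _rows(path, n_cols=3):
        tax, gene, pmid = fields[0].strip(), fields[1].strip(), fields[2].strip()
        if tax != str(taxon):
            continue
        out.setdefault(gene, set()).add(pmid)
    return out


def read_pmid_list(path: str | Path) -> set[str]:
    """Read a one-ID-per-line publication list (the disease corpus)."""
    return {fields[0].strip() for _ln, fields in _rows(path, n_cols=1)}


def read_expression(path: str | Path, dedup: str = "error") -> ExpressionMatrix:
    """Read a feature x sample expression TSV.

    First row is the sample header; each following row is a feature ID plus
    numeric values.  Duplicate feature rows are resolved per *dedup*:
    ``"error"`` (default) raises, ``"mean"`` averages element-wise.
    """
    if dedup not in ("error", "mean"):
        raise ValueError(f"unknown dedup policy {dedup!r}")
    try:
        frame = pd.read_csv(
            path, sep="\t", comment="#", index_col=0, header=0,
            encoding="utf-8",
        )
    except ValueError as exc:
        raise FormatError(f"{path}: cannot parse expression table: {exc}") from exc
    non_numeric = [c for c in frame.columns if not pd.api.types.is_numeric_dtype(frame[c])]
    if non_numeric:
        raise FormatError(
            f"{path}: non-numeric expression values in columns {non_numeric}"
        )
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if frame.index.has_duplicates:
        if dedup == "error":
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise FormatError(f"{path}: duplicate feature rows: {dups}")
        frame = frame.groupby(level=0, sort=False).mean()
    if frame.shape[1] < 3:
        raise FormatError(
            f"{path}: correlation needs >= 3 samples, file has {frame.shape[1]}"
        )
    return ExpressionMatrix(frame)


def read_predictions(path: str | Path) -> PredictionTable:
    """Read a two-column miRNA -> target prediction TSV (duplicates collapse)."""
    pairs = [
        (fields[0].strip(), fields[1].strip())
        for _ln, fields in _rows(path, n_cols=2)
    ]
    return PredictionTable(pairs)


def read_ppi(path: str | Path) -> PPINetwork:
    """Read a two-column PPI edge TSV; self-loops dropped with a logged count."""
    edges = [
        (fields[0].strip(), fields[1].strip())
        for _ln, fields in _rows(path, n_cols=2)
    ]
    net = PPINetwork(edges)
    if net.n_self_loops_dropped:
        logger.info(
            "read_ppi(%s): dropped %d self-loop(s)", path, net.n_self_loops_dropped
        )
    return net


def read_go_annotations(
    path: str | Path, gene_col: int = 0, term_col: int = 1
) -> GOAnnotationMap:
    """Read a GAF-like annotation TSV using the designated gene/term columns."""
    n_cols = max(gene_col, term_col) + 1
    pairs = [
        (fields[gene_col].strip(), fields[term_col].strip())
        for _ln, fields in _rows(path, n_cols=n_cols)
    ]
    return GOAnnotationMap(pairs)


# ---------------------------------------------------------------------------
# SIF (Cytoscape Simple Interaction Format)

#: relation labels used in SIF output
SIF_TARGETS = "targets"
SIF_INTERACTS = "interacts"


def write_subnetwork_sif(subnet: Subnetwork, path: str | Path) -> None:
    """Write a subnetwork as SIF lines ``source <relation> target``.

    miRNA -> gene arcs get the ``targets`` relation; gene-gene arcs (PPI,
    present in both directions in the analysis graph) are written once as an
    undirected ``interacts`` line.
    """
    if subnet.n_nodes == 0:
        raise ValueError("refusing to write an empty subnetwork")
    lines: list[str] = []
    seen_ppi: set[tuple[str, str]] = set()
    for u, v in sorted(subnet.graph.edges):
        if is_mirna(u):
            lines.append(f"{u}\t{SIF_TARGETS}\t{v}")
        else:
            key = (u, v) if u < v else (v, u)
            if key in seen_ppi:
                continue
            seen_ppi.add(key)
            lines.append(f"{key[0]}\t{SIF_INTERACTS}\t{key[1]}")
    for node in sorted(subnet.graph.nodes):
        if subnet.graph.degree(node) == 0:
            lines.append(node)  # isolated node: bare-name SIF line
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_sif(path: str | Path):
    """Read a SIF file back into (nodes, targets_arcs, interacts_edges)."""
    nodes: set[str] = set()
    targets: set[tuple[str, str]] = set()
    interacts: set[tuple[str, str]] = set()
    for lineno, fields in _rows(path):
        if len(fields) == 1:
            nodes.add(fields[0].strip())
            continue
        if len(fields) != 3:
            raise FormatError(f"{path}: line {lineno}: SIF line needs 1 or 3 fields")
        src, rel, dst = (f.strip() for f in fields)
        nodes.update((src, dst))
        if rel == SIF_TARGETS:
            targets.add((src, dst))
        elif rel == SIF_INTERACTS:
            interacts.add((src, dst) if src < dst else (dst, src))
        else:
            raise FormatError(f"{path}: line {lineno}: unknown relation {rel!r}")
    return nodes, targets, interacts


# ---------------------------------------------------------------------------
# Pipeline artifact tables (edge TSV, literature CSV, ranking CSV)

def write_network_tsv(net: RegulatoryNetwork, path: str | Path) -> None:
    """Write the regulatory network as a TSV: miRNA, gene, rho, p, origin."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna\tgene\trho\tp_value\torigin\n")
        for key in sorted(net.edges):
            e = net.edges[key]
            fh.write(f"{e.mirna}\t{e.gene}\t{e.rho:.10g}\t{e.p_value:.10g}\t{e.origin}\n")


def read_network_tsv(path: str | Path) -> RegulatoryNetwork:
    net = RegulatoryNetwork()
    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            net.add_edge(
                row["mirna"], row["gene"], float(row["rho"]),
                float(row["p_value"]), row["origin"],
            )
    net.extended = any(e.origin == "added" for e in net.edges.values())
    return net


def write_ranking_csv(records: list[RankRecord], path: str | Path) -> None:
    """Write the ranking report (seed, nr_nodes, RSs, Ds, PMs).

    Display columns are rounded to two decimals as in the report
    layout; full-precision companions are kept alongside.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["seed", "nr_nodes", "RSs", "Ds", "PMs", "RSs_full", "Ds_full", "PMs_full"]
        )
        for r in records:
            writer.writerow(
                [
                    r.seed, r.nr_nodes,
                    f"{r.rs:.2f}", f"{r.ds:.2f}", f"{r.pm:.2f}",
                    f"{r.rs:.10g}", f"{r.ds:.10g}", f"{r.pm:.10g}",
                ]
            )
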