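"""Deterministic synthetic fixtures with planted signal.

Emulates the five external inputs of the pipeline - a gene-publication
map with a disease corpus, a miRNA-target prediction table, paired
expression matrices, a PPI edge list and GO annotations - at desk scale,
with known ground truth written to a manifest:

* planted disease genes receive disease publications at ``pub_enrichment``
  times the corpus base rate, so they pass the literature filter;
* planted (miRNA, target) pairs have expression generated as
  ``target = effect_rho * mirna + sqrt(1 - effect_rho^2) * noise`` so the
  population correlation equals ``effect_rho``; decoy pairs are predicted
  but independent;
* a planted GO term covers ``planted_term_coverage`` of the planted pair
  targets (the background-enriched seeds) against a ~10% background rate;
* the PPI graph carries hand-placed interactors around the first planted
  targets: two fully qualifying depth-1 interactors, a depth-2 gene with
  identical qualifications (which must never be considered), a depth-1
  interactor without any GO term, and one without a prediction.

Everything is driven by one ``numpy`` generator seeded from ``rng_seed``;
the same spec always produces byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats

#: distinguished interactor gene names planted into the PPI graph
INT_ADMISSIBLE = ("INTAD1", "INTAD2")
INT_DEPTH2 = "INTD2"
INT_NO_TERM = "INTNOGO"
INT_NO_PREDICTION = "INTNOPRED"

PLANTED_TERM = "GO:0000001"
TAXON = "9606"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset (defaults are the study conditions)."""

    rng_seed: int = 0
    n_genes: int = 400
    n_mirnas: int = 25
    n_samples: int = 100
    n_disease_genes: int = 110
    pub_enrichment: float = 10.0
    n_planted_pairs: int = 50
    effect_rho: float = -0.8
    n_decoy_pairs: int = 50
    ppi_density: float = 0.02
    module_ppi_density: float = 0.3
    n_go_terms: int = 20
    planted_term_coverage: float = 0.8

    def __post_init__(self):
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if not -1.0 < self.effect_rho < 0.0:
            raise ValueError("effect_rho must lie in (-1, 0)")
        if self.n_planted_pairs + self.n_decoy_pairs > self.n_disease_genes:
            raise ValueError(
                "need n_disease_genes >= n_planted_pairs + n_decoy_pairs "
                "(each pair gets its own disease-gene target)"
            )
        if self.n_disease_genes > self.n_genes:
            raise ValueError("n_disease_genes cannot exceed n_genes")
        if not 0.0 < self.ppi_density < 1.0:
            raise ValueError("ppi_density must lie in (0, 1)")
        if not 0.0 < self.planted_term_coverage <= 1.0:
            raise ValueError("planted_term_coverage must lie in (0, 1]")
        power = detection_power(abs(self.effect_rho), self.n_samples)
        if power < 0.9:
            raise ValueError(
                f"correlation detection power {power:.3f} < 0.9 at "
                f"n_samples={self.n_samples}, |effect_rho|={abs(self.effect_rho)}; "
                "increase n_samples or |effect_rho|"
            )


def detection_power(rho: float, n_samples: int, alpha: float = 0.05) -> float:
    """Approximate power of the two-sided correlation test (Fisher z)."""
    if n_samples < 4:
        raise ValueError("need n_samples >= 4")
    z_effect = math.atanh(rho) * math.sqrt(n_samples - 3)
    z_crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    return float(stats.norm.cdf(z_effect - z_crit))


def _gene_names(spec: FixtureSpec) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(spec.n_genes)]


def _mirna_names(spec: FixtureSpec) -> list[str]:
    return [f"hsa-miR-{i + 1:03d}" for i in range(spec.n_mirnas)]


def generate(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write the five input files plus a ground-truth manifest.

    Returns the manifest (also written to ``manifest.json``), augmented
    with a ``"paths"`` entry mapping logical input names to file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed)

    genes = _gene_names(spec)
    mirnas = _mirna_names(spec)
    disease_genes = genes[: spec.n_disease_genes]
    planted_targets = disease_genes[: spec.n_planted_pairs]
    decoy_targets = disease_genes[
        spec.n_planted_pairs : spec.n_planted_pairs + spec.n_decoy_pairs
    ]
    int_genes = list(INT_ADMISSIBLE) + [INT_DEPTH2, INT_NO_TERM, INT_NO_PREDICTION]

    # -- literature ---------------------------------------------------------
    disease_pool = [f"D{i + 1:05d}" for i in range(200)]
    base_pool = [f"N{i + 1:05d}" for i in range(4000)]
    base_rate = len(disease_pool) / (len(disease_pool) + len(base_pool))
    enriched_rate = min(0.9, base_rate * spec.pub_enrichment)

    gene_pubs: dict[str, list[str]] = {}
    j_disease = 30
    k_disease = int(round(enriched_rate * j_disease))
    for g in disease_genes:
        dis = rng.choice(len(disease_pool), size=k_disease, replace=False)
        oth = rng.choice(len(base_pool), size=j_disease - k_disease, replace=False)
        gene_pubs[g] = sorted(
            [disease_pool[i] for i in dis] + [base_pool[i] for i in oth]
        )
    combined_pool = disease_pool + base_pool
    for g in genes[spec.n_disease_genes :]:
        j = int(rng.integers(8, 17))
        idx = rng.choice(len(combined_pool), size=j, replace=False)
        gene_pubs[g] = sorted(combined_pool[i] for i in idx)
    # interactor genes are deliberately unpublished (novel-candidate story)

    # -- predictions --------------------------------------------------------
    # planted targets are assigned to miRNAs in consecutive blocks, so
    # block-mates share their regulator (the raw material for triangles
    # once module PPI edges are added)
    block = max(1, math.ceil(spec.n_planted_pairs / spec.n_mirnas))
    planted_pairs = [
        (mirnas[(i // block) % spec.n_mirnas], t)
        for i, t in enumerate(planted_targets)
    ]
    decoy_pairs = [
        (mirnas[(i + 7) % spec.n_mirnas], t) for i, t in enumerate(decoy_targets)
    ]
    mir_int = [mirnas[0], mirnas[1 % spec.n_mirnas]]
    prediction_rows = set(planted_pairs) | set(decoy_pairs)
    prediction_rows |= {
        (mir_int[0], INT_ADMISSIBLE[0]),
        (mir_int[1], INT_ADMISSIBLE[1]),
        (mir_int[0], INT_DEPTH2),
        (mir_int[0], INT_NO_TERM),
    }

    # -- expression ---------------------------------------------------------
    samples = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    mirna_expr = {m: rng.standard_normal(spec.n_samples) for m in mirnas}

    rho = spec.effect_rho
    noise_scale = math.sqrt(1.0 - rho * rho)

    def anticorrelated(driver: np.ndarray) -> np.ndarray:
        return rho * driver + noise_scale * rng.standard_normal(spec.n_samples)

    mrna_expr: dict[str, np.ndarray] = {}
    for (m, t) in planted_pairs:
        mrna_expr[t] = anticorrelated(mirna_expr[m])
    for g in genes:
        if g not in mrna_expr:
            mrna_expr[g] = rng.standard_normal(spec.n_samples)
    anchor = mir_int[0] if not planted_pairs else planted_pairs[0][0]
    mrna_expr[INT_ADMISSIBLE[0]] = anticorrelated(mirna_expr[mir_int[0]])
    mrna_expr[INT_ADMISSIBLE[1]] = anticorrelated(mirna_expr[mir_int[1]])
    mrna_expr[INT_DEPTH2] = anticorrelated(mirna_expr[mir_int[0]])
    mrna_expr[INT_NO_TERM] = anticorrelated(mirna_expr[mir_int[0]])
    mrna_expr[INT_NO_PREDICTION] = anticorrelated(mirna_expr[anchor])

    # -- PPI ----------------------------------------------------------------
    # random graph over the regular genes; planted interactors are wired by
    # hand so their BFS depths are exactly known
    ppi_edges: set[tuple[str, str]] = set()
    for i in range(spec.n_genes):
        for j in range(i + 1, spec.n_genes):
            if rng.random() < spec.ppi_density:
                ppi_edges.add((genes[i], genes[j]))
    # denser interactions inside the disease module: targets sharing a
    # regulator interact at module_ppi_density, closing miRNA-target-target
    # triangles in the analysis graph
    by_mirna: dict[str, list[str]] = {}
    for m, t in planted_pairs:
        by_mirna.setdefault(m, []).append(t)
    for m in sorted(by_mirna):
        mates = by_mirna[m]
        for i in range(len(mates)):
            for j in range(i + 1, len(mates)):
                if rng.random() < spec.module_ppi_density:
                    ppi_edges.add(tuple(sorted((mates[i], mates[j]))))
    anchor_targets = (planted_targets or decoy_targets or disease_genes)[:2]
    if len(anchor_targets) == 1:
        anchor_targets = anchor_targets * 2
    ppi_edges |= {
        (anchor_targets[0], INT_ADMISSIBLE[0]),
        (anchor_targets[1], INT_ADMISSIBLE[1]),
        (INT_ADMISSIBLE[0], INT_DEPTH2),
        (anchor_targets[0], INT_NO_TERM),
        (anchor_targets[1], INT_NO_PREDICTION),
    }

    # -- GO annotations -----------------------------------------------------
    # the planted term covers planted_term_coverage of the disease genes,
    # stratified so both the pair targets and the remaining disease genes
    # are covered at the same rate; uncovered pair targets act as the
    # background-decoy seeds for ranking checks
    n_enriched = int(round(spec.planted_term_coverage * len(planted_targets)))
    enriched_seeds = planted_targets[:n_enriched]
    decoy_seeds = planted_targets[n_enriched:]
    other_disease = [g for g in disease_genes if g not in planted_targets]
    n_other = int(round(spec.planted_term_coverage * len(other_disease)))
    covered = enriched_seeds + other_disease[:n_other]
    annotations: set[tuple[str, str]] = {(g, PLANTED_TERM) for g in covered}
    annotations |= {
        (INT_ADMISSIBLE[0], PLANTED_TERM),
        (INT_ADMISSIBLE[1], PLANTED_TERM),
        (INT_DEPTH2, PLANTED_TERM),
        (INT_NO_PREDICTION, PLANTED_TERM),
    }
    go_terms = [f"GO:{i + 2:07d}" for i in range(spec.n_go_terms)]
    annotatable = genes + int_genes
    for term in go_terms:
        for g in annotatable:
            if g == INT_NO_TERM:
                continue
            if rng.random() < 0.10:
                annotations.add((g, term))
    # every gene needs some annotation so the universe covers the network
    annotated = {g for g, _ in annotations}
    for g in annotatable:
        if g == INT_NO_TERM:
            continue
        if g not in annotated:
            annotations.add((g, go_terms[0]))

    # -- write files --------------------------------------------------------
    paths = {
        "gene2pubmed": out / "gene2pubmed.tsv",
        "disease_pmids": out / "disease_pmids.txt",
        "predictions": out / "predictions.tsv",
        "mrna": out / "mrna.tsv",
        "mirna": out / "mirna.tsv",
        "ppi": out / "ppi.tsv",
        "go": out / "go_annotations.tsv",
    }
    with open(paths["gene2pubmed"], "w", encoding="utf-8") as fh:
        fh.write("# tax_id\tgene\tpubmed_id\n")
        for g in sorted(gene_pubs):
            for pmid in gene_pubs[g]:
                fh.write(f"{TAXON}\t{g}\t{pmid}\n")
    with open(paths["disease_pmids"], "w", encoding="utf-8") as fh:
        fh.write("\n".join(disease_pool) + "\n")
    with open(paths["predictions"], "w", encoding="utf-8") as fh:
        fh.write("# mirna\tgene\n")
        for m, t in sorted(prediction_rows):
            fh.write(f"{m}\t{t}\n")
    with open(paths["ppi"], "w", encoding="utf-8") as fh:
        fh.write("# interactor_a\tinteractor_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in ppi_edges):
            fh.write(f"{a}\t{b}\n")
    with open(paths["go"], "w", encoding="utf-8") as fh:
        fh.write("# gene\tgo_term\n")
        for g, term in sorted(annotations):
            fh.write(f"{g}\t{term}\n")

    def write_expr(path: Path, rows: dict[str, np.ndarray], order: list[str]):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("feature\t" + "\t".join(samples) + "\n")
            for name in order:
                vals = "\t".join(f"{v:.6f}" for v in rows[name])
                fh.write(f"{name}\t{vals}\n")

    write_expr(paths["mrna"], mrna_expr, genes + int_genes)
    write_expr(paths["mirna"], mirna_expr, mirnas)

    manifest = {
        "params": asdict(spec),
        "disease_genes": disease_genes,
        "planted_pairs": [list(p) for p in planted_pairs],
        "decoy_pairs": [list(p) for p in decoy_pairs],
        "enriched_seed_genes": enriched_seeds,
        "decoy_seed_genes": decoy_seeds,
        "planted_term": PLANTED_TERM,
        "interactors": {
            "admissible_depth1": list(INT_ADMISSIBLE),
            "admissible_mirnas": mir_int,
            "depth2": INT_DEPTH2,
            "no_term_depth1": INT_NO_TERM,
            "no_prediction_depth1": INT_NO_PREDICTION,
            "anchor_targets": list(anchor_targets),
        },
        "mirnas": mirnas,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["paths"] = {k: str(v) for k, v in paths.items()}
    return manifest
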