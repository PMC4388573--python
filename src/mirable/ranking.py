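"""Regulatory subnetwork scoring and the final seed ranking.

Each subnetwork is enriched against the disease Background Functions: for
every background term f the same enrichment p-value as in the background
selection is computed, but with the subnetwork's gene nodes as the query
set (miRNA nodes are excluded - GO annotates genes).  The vector v of
per-term p-values is collapsed Fisher-combined-probability style:

    S(v) = sum over i with v_i > 0 of -log10(v_i)

Terms with p exactly 1 contribute nothing; no multiple-testing adjustment
is applied at this stage (BH enters only when the background itself is
selected).  Seeds are ranked by S(v) descending.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

from .datatypes import (
    BackgroundFunctions,
    DiseaseScoreRecord,
    GOAnnotationMap,
    RankRecord,
    Subnetwork,
    is_mirna,
)
from .enrichment import enrichment_pvalue

logger = logging.getLogger(__name__)

#: p-values that underflowed to zero are floored here before the log.
P_FLOOR = 1e-320

#: minimum supporting disease publications for a gene's disease score to be
#: reported; below it the -1.00 sentinel is shown.
MIN_SUPPORTING_PUBS = 9

#: sentinel disease score for miRNA seeds and under-published genes.
DS_SENTINEL = -1.0


def subnetwork_score(
    subnet: Subnetwork,
    bf: BackgroundFunctions,
    ann: GOAnnotationMap,
    mode: str = "paper",
) -> float:
    """Fisher-combined background-function score S(v) of one subnetwork."""
    if len(bf) == 0:
        return 0.0
    universe = ann.universe
    q = subnet.gene_nodes & universe
    m = len(universe)
    n = len(q)
    score = 0.0
    for term in bf:
        k = len(q & ann.genes_for(term))
        j = len(ann.genes_for(term))
        p = enrichment_pvalue(k, j, n, m, mode=mode)
        if p >= 1.0:
            continue
        score += -math.log10(max(p, P_FLOOR))
    return score


def score_all_subnetworks(
    subnets: Mapping[str, Subnetwork],
    bf: BackgroundFunctions,
    ann: GOAnnotationMap,
    mode: str = "paper",
) -> dict[str, float]:
    return {
        seed: subnetwork_score(sub, bf, ann, mode=mode)
        for seed, sub in subnets.items()
    }


def _display_ds(seed: str, lit_records: Mapping[str, DiseaseScoreRecord]) -> float:
    """Disease-score column value with the -1.00 sentinel rule applied."""
    if is_mirna(seed):
        return DS_SENTINEL
    rec = lit_records.get(seed)
    if rec is None or rec.n_pubs < MIN_SUPPORTING_PUBS:
        return DS_SENTINEL
    return rec.ds


def rank_seeds(
    subnets: Mapping[str, Subnetwork],
    scores: Mapping[str, float],
    meta_pm: Mapping[str, float],
    lit_records: Mapping[str, DiseaseScoreRecord],
) -> list[RankRecord]:
    """Rank every seed by its subnetwork score, highest first.

    Ties on the score are broken by subnetwork size descending, then seed
    ID ascending.  The disease-score column shows -1.00 for miRNA seeds and
    for genes with fewer than the reporting minimum of supporting
    publications; the power-method column comes from the meta-network.
    """
    records = [
        RankRecord(
            seed=seed,
            nr_nodes=subnets[seed].n_nodes,
            rs=float(scores[seed]),
            ds=_display_ds(seed, lit_records),
            pm=float(meta_pm.get(seed, 0.0)),
        )
        for seed in subnets
    ]
    records.sort(key=lambda r: (-r.rs, -r.nr_nodes, r.seed))
    return records
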