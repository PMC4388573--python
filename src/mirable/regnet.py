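"""Construction of the base regulatory network RC.

A predicted (miRNA, target) pair enters the network when the target is a
disease gene, the pair's expression Pearson correlation is negative, and
its absolute value reaches the smallest magnitude that is statistically
significant at the chosen level for the given sample count:

    RC = {(m, t) | m in P(t), t in GS(D),
                   |rho(m, t)| >= |min_corr|, rho(m, t) < 0}
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np
from scipy import stats

from .datatypes import (
    CorrelationResult,
    ExpressionMatrix,
    PredictionTable,
    RegulatoryNetwork,
)

logger = logging.getLogger(__name__)


def pearson(x: Iterable[float], y: Iterable[float]) -> CorrelationResult:
    """Pearson correlation with the exact two-sided t-test p-value.

    Either vector having zero variance yields an "undefined correlation"
    result (``ok=False``); such pairs always fail the network filter.
    """
    xv = np.asarray(list(x), dtype=float)
    yv = np.asarray(list(y), dtype=float)
    if xv.shape != yv.shape:
        raise ValueError(f"length mismatch: {xv.shape} vs {yv.shape}")
    n = xv.size
    if n < 3:
        raise ValueError(f"need >= 3 paired samples, got {n}")
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        return CorrelationResult(
            rho=float("nan"), n_samples=n, p_value=float("nan"),
            ok=False, reason="undefined correlation (zero variance)",
        )
    res = stats.pearsonr(xv, yv)
    return CorrelationResult(
        rho=float(res.statistic), n_samples=n, p_value=float(res.pvalue)
    )


def min_significant_corr(n_samples: int, alpha: float = 0.05) -> float:
    """Smallest |r| that is two-sided significant at *alpha* for n samples.

    Inverts the t transform t = r sqrt((n-2)/(1-r^2)):
    r = t_crit / sqrt(n - 2 + t_crit^2), monotone decreasing in n.
    """
    if n_samples < 4:
        raise ValueError(f"need >= 4 samples for a meaningful cutoff, got {n_samples}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    df = n_samples - 2
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    return t_crit / math.sqrt(df + t_crit**2)


def _check_same_samples(mrna: ExpressionMatrix, mirna: ExpressionMatrix) -> None:
    if list(mrna.samples) != list(mirna.samples):
        raise ValueError(
            "mRNA and miRNA expression matrices must share identical sample "
            "IDs in identical order"
        )


def build_regulatory_network(
    genes: Iterable[str],
    preds: PredictionTable,
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    alpha: float = 0.05,
) -> RegulatoryNetwork:
    """Build the base bipartite network over the disease gene set.

    Edges are exactly the predicted pairs with a significant negative
    expression correlation; nodes are the endpoints of retained edges.
    Genes or miRNAs absent from the expression matrices are skipped (the
    correlation predicate is undefined for them) and counted in the log.
    """
    _check_same_samples(mrna, mirna)
    n = mrna.n_samples
    threshold = min_significant_corr(n, alpha)
    net = RegulatoryNetwork(alpha=alpha, min_corr=threshold, n_samples=n)

    gene_set = sorted(set(str(g) for g in genes))
    n_skipped_genes = sum(1 for g in gene_set if g not in mrna)
    skipped_mirnas: set[str] = set()
    for t in gene_set:
        if t not in mrna:
            continue
        tx = mrna.vector(t)
        for m in sorted(preds.mirnas_for(t)):
            if m not in mirna:
                skipped_mirnas.add(m)
                continue
            corr = pearson(tx, mirna.vector(m))
            if not corr.ok:
                continue
            if corr.rho < 0.0 and abs(corr.rho) >= threshold:
                net.add_edge(m, t, corr.rho, corr.p_value, origin="literature")
    logger.info(
        "build_regulatory_network: %d edges, %d miRNAs, %d targets "
        "(min_corr=%.4f at alpha=%g, n=%d); skipped %d unexpressed genes, "
        "%d unexpressed miRNAs",
        len(net), len(net.mirnas), len(net.targets), threshold, alpha, n,
        n_skipped_genes, len(skipped_mirnas),
    )
    return net
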