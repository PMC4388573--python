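"""GO functional enrichment and the disease Background Functions.

Counts follow the method's contingency layout for a term f against a
query gene set Q inside universe G_GO:

    k = #(f, Q)        genes of Q annotated with f
    j = #(f, G_GO)     genes of the universe annotated with f
    n = |Q|            query size
    m = |G_GO|         universe size

Two p-value modes are provided.  ``"paper"`` evaluates the closed form

    Fisher(f, Q) = C(k+j, k) * C(n-k+m-j, n-k) / C(n+m, n)

taken literally from the method's definition (note its margins double-count: j
includes k and m includes the query's genes, so this is not a standard
Fisher exact test).  ``"standard"`` is the conventional one-sided Fisher
exact test, i.e. the hypergeometric upper tail of k.  The Background
Functions are the terms whose Benjamini-Hochberg-adjusted p-value is at or
below alpha.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .datatypes import BackgroundFunctions, EnrichmentResult, GOAnnotationMap
from .literature import _log_comb, hypergeom_tail

logger = logging.getLogger(__name__)

MODES = ("paper", "standard")


def fisher_paper(k: int, j: int, n: int, m: int) -> float:
    """Literal evaluation of the method's defining enrichment formula, in log space.

    Results outside [0, 1] (possible because these margins are not a
    consistent 2x2 table) are clamped to 1 with a warning.
    """
    if min(k, j, n, m) < 0:
        raise ValueError(f"negative count in (k={k}, j={j}, n={n}, m={m})")
    log_p = (
        _log_comb(k + j, k)
        + _log_comb(n - k + m - j, n - k)
        - _log_comb(n + m, n)
    )
    if log_p == float("-inf"):
        # a binomial outside its support: treat as an impossible table
        warnings.warn(
            f"enrichment formula undefined for (k={k}, j={j}, n={n}, m={m}); "
            "clamping p to 1",
            stacklevel=2,
        )
        return 1.0
    if log_p > 0.0:
        warnings.warn(
            f"enrichment formula exceeded 1 for (k={k}, j={j}, n={n}, m={m}); "
            "clamping p to 1",
            stacklevel=2,
        )
        return 1.0
    return math.exp(log_p)


def fisher_standard(k: int, j: int, n: int, m: int) -> float:
    """One-sided (enrichment) Fisher exact p-value for the corrected table.

    The corrected 2x2 table is [k, j-k; n-k, m-j-(n-k)]; the p-value is the
    hypergeometric upper tail P(X >= k) when drawing n genes from a universe
    of m containing j annotated ones.
    """
    if min(k, j, n, m) < 0:
        raise ValueError(f"negative count in (k={k}, j={j}, n={n}, m={m})")
    if j - k < 0 or n - k < 0 or m - j - (n - k) < 0 or n > m or j > m:
        raise ValueError(
            f"counts (k={k}, j={j}, n={n}, m={m}) do not form a consistent "
            "2x2 table"
        )
    return hypergeom_tail(m, n, j, k)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def enrichment_pvalue(k: int, j: int, n: int, m: int, mode: str = "paper") -> float:
    if mode not in MODES:
        raise ValueError(f"unknown enrichment mode {mode!r}; choose from {MODES}")
    return fisher_paper(k, j, n, m) if mode == "paper" else fisher_standard(k, j, n, m)


def background_functions(
    query: Iterable[str],
    ann: GOAnnotationMap,
    alpha: float = 0.05,
    mode: str = "paper",
) -> BackgroundFunctions:
    """Select the disease Background Functions F_BF(D).

    Only terms annotating at least one query gene are tested; the BH family
    size is the number of tested terms.  Query genes outside the annotation
    universe are ignored (they can never contribute to a term count).
    """
    universe = ann.universe
    q = frozenset(str(g) for g in query) & universe
    if not q:
        logger.warning(
            "background_functions: query has no overlap with the annotation "
            "universe; empty result"
        )
        return BackgroundFunctions({})
    m = len(universe)
    n = len(q)
    tested: list[tuple[str, int, int, float]] = []
    for term in sorted(ann.terms):
        genes_f = ann.genes_for(term)
        k = len(q & genes_f)
        if k == 0:
            continue
        j = len(genes_f)
        tested.append((term, k, j, enrichment_pvalue(k, j, n, m, mode)))
    if not tested:
        return BackgroundFunctions({})
    adjusted = bh_adjust([p for _, _, _, p in tested])
    results = {
        term: EnrichmentResult(term=term, k=k, j=j, n=n, m=m, p_raw=p, p_adj=q_adj)
        for (term, k, j, p), q_adj in zip(tested, adjusted)
        if q_adj <= alpha
    }
    logger.info(
        "background_functions: %d/%d tested terms retained at BH alpha=%g "
        "(mode=%s, |query|=%d, universe=%d)",
        len(results), len(tested), alpha, mode, n, m,
    )
    return BackgroundFunctions(results)
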