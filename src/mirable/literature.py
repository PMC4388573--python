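"""Literature-based disease scoring of genes.

Each gene is scored against a disease publication corpus with the upper
tail of the hypergeometric distribution: given m articles carrying human
gene information, n of which are disease-related, a gene discussed in j
articles of which k are disease-related has

    H(m, n, j, k) = sum_{i=k}^{min(n,j)} C(m-j, n-i) C(j, i) / C(m, n)
    ds(m, n, j, k) = -log10 H(m, n, j, k)

Genes with ds strictly above a threshold (default 4) form the disease gene
set that seeds the regulatory network.  The tail is evaluated in log space
so that the extremely small probabilities of heavily published disease
genes survive without underflow.
"""

from __future__ import annotations

import math

from scipy.special import gammaln, logsumexp

from .datatypes import DiseaseScoreRecord, LiteratureCounts

#: Disease score reported when the tail probability underflows to zero in
#: double precision (below ~1e-320 the -log10 is no longer representable
#: through the probability itself).
DS_CAP = 320.0

_LN10 = math.log(10.0)


def _log_comb(n: int, k: int) -> float:
    """log C(n, k); -inf outside the support."""
    if k < 0 or k > n or n < 0:
        return float("-inf")
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def _log_hypergeom_tail(m: int, n: int, j: int, k: int) -> float:
    """Natural log of H(m, n, j, k); -inf for an empty sum."""
    if min(m, n, j, k) < 0:
        raise ValueError(f"negative count in (m={m}, n={n}, j={j}, k={k})")
    if n > m or j > m:
        raise ValueError(f"need n <= m and j <= m, got (m={m}, n={n}, j={j})")
    hi = min(n, j)
    if k <= 0:
        return 0.0  # full support: the tail sums to exactly 1 (Vandermonde)
    if k > hi:
        return float("-inf")
    log_denom = _log_comb(m, n)
    terms = [
        _log_comb(m - j, n - i) + _log_comb(j, i) - log_denom
        for i in range(k, hi + 1)
    ]
    terms = [t for t in terms if t != float("-inf")]
    if not terms:
        return float("-inf")
    return min(0.0, float(logsumexp(terms)))


def hypergeom_tail(m: int, n: int, j: int, k: int) -> float:
    """Upper-tail probability H(m, n, j, k), in [0, 1].

    k <= 0 gives exactly 1.0; k > min(n, j) gives 0.0 (empty sum).  May
    underflow to 0.0 for extreme enrichment; use :func:`disease_score` when
    the -log10 scale is what matters.
    """
    return math.exp(_log_hypergeom_tail(m, n, j, k))


def disease_score(m: int, n: int, j: int, k: int) -> float:
    """Disease score ds = -log10 H(m, n, j, k), capped at :data:`DS_CAP`.

    Computed from the log-space tail directly, so scores up to the cap are
    exact even when the probability itself underflows.
    """
    log_tail = _log_hypergeom_tail(m, n, j, k)
    if log_tail == float("-inf"):
        return DS_CAP
    ds = -log_tail / _LN10
    return min(DS_CAP, max(0.0, ds))


def literature_counts(
    gene_pubs: dict[str, set[str]], disease_pmids: set[str]
) -> tuple[int, int]:
    """Corpus-level counts (m, n) from the supplied publication maps.

    m is the number of distinct articles carrying gene information, n the
    subset of those that are disease-related.
    """
    all_pubs: set[str] = set()
    for pubs in gene_pubs.values():
        all_pubs |= pubs
    m = len(all_pubs)
    n = len(all_pubs & disease_pmids)
    return m, n


def score_genes(
    gene_pubs: dict[str, set[str]], disease_pmids: set[str]
) -> dict[str, DiseaseScoreRecord]:
    """Disease-score every gene in *gene_pubs* against the disease corpus."""
    if not disease_pmids:
        raise ValueError("empty disease publication set: score undefined")
    m, n = literature_counts(gene_pubs, disease_pmids)
    records: dict[str, DiseaseScoreRecord] = {}
    for gene in sorted(gene_pubs):
        pubs = gene_pubs[gene]
        j = len(pubs)
        k = len(pubs & disease_pmids)
        counts = LiteratureCounts(m=m, n=n, j=j, k=k)
        records[gene] = DiseaseScoreRecord(
            gene=gene,
            counts=counts,
            H=hypergeom_tail(m, n, j, k),
            ds=disease_score(m, n, j, k),
        )
    return records


def select_disease_genes(
    gene_pubs: dict[str, set[str]],
    disease_pmids: set[str],
    threshold: float = 4.0,
) -> dict[str, DiseaseScoreRecord]:
    """Genes whose disease score is strictly greater than *threshold*."""
    records = score_genes(gene_pubs, disease_pmids)
    return {g: r for g, r in records.items() if r.ds > threshold}
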