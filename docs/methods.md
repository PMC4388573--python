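# Methods

## Model and assumptions

`mirable` treats disease relevance as three composable sources of
evidence: co-citation with the disease in the literature, sequence-based
miRNA-target prediction confirmed by expression anticorrelation, and
guilt-by-association through physical interaction plus shared disease
function. The repression model is linear: a regulating miRNA is assumed to
depress its target's steady-state mRNA level monotonically across
samples, so Pearson correlation on normalised expression is the filter
statistic. No causal claim is made; the output is a prioritisation.

## Statistics

**Literature disease score.** ds = −log10 of the hypergeometric upper
tail H(m, n, j, k). The tail is evaluated in log space (log-gamma
binomials combined with log-sum-exp), so the score of a heavily published
gene is exact even when the probability itself underflows double
precision; only when the tail drops below ~1e−320 is the score capped, at
`DS_CAP = 320`. Corpus counts m and n are always computed from the
supplied files (m = distinct articles carrying gene information, n = the
disease-related subset), never taken as constants, so runs on any corpus
are self-consistent. The selection rule is strictly ds > threshold
(default 4). A "≥ 9 supporting publications" notion exists only in the
final report, where a gene below it shows the −1.00 sentinel instead of
its score; it filters nothing.

**Correlation significance.** The p-value of ρ is the exact two-sided
t-transform with n−2 degrees of freedom (via `scipy.stats.pearsonr`). The
admission threshold min_corr inverts that transform:
r = t_crit / sqrt(n−2+t_crit²) at t_crit = t⁻¹(1−α/2, n−2). Two-sided is
the conservative reading given that the sign constraint ρ < 0 is applied
separately; ties at |ρ| = min_corr are retained. Pairs with a
zero-variance vector have no defined correlation and always fail the
filter. Both expression matrices must share the same samples in the same
order; anything else is a hard error rather than a silent join.

**Enrichment.** Two p-value modes ship. `paper` evaluates the literal
closed form C(k+j,k)·C(n−k+m−j,n−k)/C(n+m,n); its margins double-count
(j includes k, m includes the query's genes), so it is not a standard
Fisher exact test, but it is kept as the default because it is the
formula the method is defined with. `standard` is the conventional
one-sided Fisher exact test, i.e. the hypergeometric upper tail of k in
the corrected 2×2 table. The two agree on ordering in the regimes the
pipeline meets (term coverage well under half the universe) and both are
exposed via configuration. Only terms annotating ≥ 1 query gene are
tested, and the Benjamini–Hochberg family is the tested set (testing
untouched terms would only dilute the adjustment). GO is used as a flat
annotation map: no ancestor propagation, no DAG parsing.

**Subnetwork score.** S(v) sums −log10 of the *raw* per-term p-values of
the subnetwork's gene set against each background function; BH is applied
only when the background itself is selected. miRNA nodes are excluded
from the query (GO annotates genes). Terms at p = 1 contribute nothing;
p-values that underflow are floored at 1e−320 before the log.

**Power method.** The iteration is x ← (A+I)x / ‖(A+I)x‖₁ from the
uniform start, converged when the L1 change drops below 1e−10 (cap 10⁵
iterations, non-convergence raises carrying the last iterate). The +I
shift leaves A's eigenvectors unchanged while shifting eigenvalues by 1,
which suppresses the sign-flip oscillation a bare iteration exhibits on
bipartite or periodic graphs — the one numerically load-bearing deviation
from the bare fixed-point equation λx = Ax. The reported λ is the
Rayleigh quotient for A. Scores are L1-normalised, so meta-network values
are comparable across runs.

## Graph conventions

Triangles are found on the undirected view of the analysis graph (the
worked toy example uses plain neighbour sets), while the induced arcs of
a subnetwork keep their directions for the centrality indices. Neighbours
that close no triangle with the seed are excluded; a seed with no
triangle keeps a singleton subnetwork so that every node receives a score
and a rank. Closeness uses the harmonic convention (unreachable pairs
contribute 0, normalised by n−1); eccentricity is the maximum distance
over the reachable set, 0 for sinks. PPI closure depth is unlimited by
default (the import stops only when no interactor is reachable), but only
depth-1 interactors are ever candidates for target addition, so closure
depth beyond 1 affects logs, not results. PPI arcs between an admitted
target and a base target do enter the analysis graph — they are
interactions among direct targets.

## Thresholds and defaults

| parameter | default | meaning |
|---|---|---|
| ds_threshold | 4 | −log10 scale; strict > |
| alpha_corr | 0.05 | two-sided correlation significance for RC |
| alpha_add | 0.01 | stricter anticorrelation for admitted targets |
| alpha_bf | 0.05 | BH-adjusted cut for background functions |
| enrichment mode | paper | literal closed form; `standard` available |
| power tol / max_iter | 1e−10 / 10⁵ | L1 convergence of the iteration |
| expression dedup | error | `mean` available; silent collapse hides probe issues |
| miRNA prefixes | hsa-miR, hsa-let | namespace split between miRNAs and genes |

## Synthetic data generator

The generator (`mirable.synth`) emulates the five inputs with planted
ground truth. Defaults are the study conditions of the recovery suite:
100 samples, planted anticorrelation ρ = −0.8 (detection power ≈ 1 at
α = 0.05; a power check at generation rejects underpowered designs),
50 planted and 50 decoy predicted pairs, each with its own disease-gene
target. Disease genes draw 30 publications with a disease fraction of
pub_enrichment × the corpus base rate (deterministic split, so every
planted gene clears the ds filter); background genes draw at the base
rate. Expression is Gaussian: planted targets are
ρ·z_miRNA + sqrt(1−ρ²)·noise, decoys independent — the linear model the
Pearson filter assumes.

Two geometry choices matter and are deliberate realism constraints, not
tuning: (1) the annotation universe (400 genes) is several times larger
than the disease set (110), as in real GO versus a disease gene list —
with a majority-disease universe the literal enrichment formula rewards
term *absence* and the scoring inverts; (2) targets sharing a regulator
interact at a higher "module" PPI density (0.3) than the background
(0.02), because disease proteins cluster — these edges are what closes
miRNA-target-target triangles and gives the subnetwork stage non-trivial
structure. Hand-wired interactors with exactly known BFS depths exercise
every branch of the target-addition rule (qualifying depth-1, identical
gene at depth-2, no-GO-term, no-prediction).

What the generator does not emulate: probe/batch effects, heavy-tailed
expression noise, GO DAG topology, scale-free PPI degree distributions,
miRNA family structure. Passing the recovery suite therefore shows the
pipeline implements its rules faithfully under its own model assumptions,
not that the method's biological findings transfer to real cohorts.

## Problem sizes

Tests and the acceptance suite run at desk scale by design: exhaustive
enumeration oracles up to a 15-article corpus and a 12-gene universe,
200 random digraphs (≤ 15 nodes) for triangle extraction, 50 random
symmetric graphs (≤ 8 nodes) against full eigendecomposition, and 20
generator seeds of the default fixture for the ranking comparison. The
full pipeline on a default fixture (400 genes, 25 miRNAs, 100 samples)
runs in well under a second.

## Known limitations

* The literal `paper` enrichment formula is not a calibrated p-value;
  ordering is meaningful, absolute magnitudes are not. Use `standard`
  when calibration matters.
* Subnetwork scores are not corrected across seeds (no FDR over
  subnetworks), matching the method's definition; ranks, not magnitudes,
  are the output.
* Expression features are assumed pre-mapped to gene symbols; no
  probe-to-gene mapping is performed.
* PPI edges are unweighted and untyped; no physical-vs-genetic filtering.
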