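# Methods

`transppi` studies how genetic variants in two interpretable classes of
genomic regions — exons, and the spans of transcription-factor (TF) genes,
introns included — associate with the expression of *distal* transcripts
(trans associations), and what those source–target gene pairs look like
when projected onto a protein–protein interaction (PPI) network.  This note
documents the models, the conventions, and the design decisions that are
not obvious from the code.

## Association model

Each SNP is tested against each transcript by ordinary least squares of
expression on additive dosage (0/1/2 minor-allele copies), with a
two-sided t-test on the slope at n−2 degrees of freedom.  Missing genotype
calls are dropped pairwise per test; no covariates or population-structure
correction are applied (the package targets small, homogeneous cohorts and
the threshold-family analyses below rather than single calibrated
discoveries).  QC uses the standard strict filters — MAF > 0.05, per-SNP
missingness < 0.1 applied before per-sample missingness < 0.1 — with MAF
recomputed from non-missing calls only.

A pair is **trans** when the target gene sits on a different chromosome
from the eSNP, or on the same chromosome with at least 1 Mb between the
SNP position and the nearest target-span boundary.  The SNP's own host
gene is always excluded.  Coordinates are 1-based with closed intervals
everywhere; a SNP on an exon boundary base is exonic.

## Network topology

The PPI graph is undirected and simple; distance is the hop count of a
shortest path (computed by per-node BFS, which the test suite proves
identical to Floyd–Warshall).  When the graph is disconnected, every
cross-component pair receives the same surrogate distance: **twice the
maximum finite distance** observed within any component (global maximum; a
per-component-pair reading was considered and rejected as ambiguous —
the global convention is documented and tested).  Recorded geodesics are
made deterministic by walking back from the target through the
lexicographically smallest predecessor in each BFS layer.

Clustering uses the Louvain modularity heuristic (networkx
implementation, seeded), with clusters renumbered by decreasing size.
Modularity is the standard Newman–Girvan Q; an edgeless graph gets the
degenerate one-node-per-cluster partition with Q reported as 0.

## Threshold trends

Candidate pairs are sorted by ascending association p; every prefix of
that list defines a threshold (−log10 p of the last pair included) and a
cumulative mean of each topological property (pair distance, source
degree, target degree).  Spearman's r between thresholds and cumulative
means summarizes each trend.  Significance is assessed against permuted
pair sets of the same size that reuse the real p-value ordering but random
network positions (uniform node pairs by default; edge-switched pairs from
the observed source/target multisets as an option).

The empirical p counts permuted correlations **strictly beyond** the real
one, divided by the number of permutations (it may be exactly 0); a
(r+1)/(n+1) pseudocount variant is available but off by default.  The
direction is property-specific — distance is tested toward smaller r,
degrees toward larger r — and the raw "permuted r > real r" count is
reported alongside.

A note on statistics: cumulative means are a random walk's running
average, so even null trend curves produce large |r| routinely.  The
permutation null absorbs exactly this autocorrelation, which is why trend
r values near ±1 can still have empirical p of only a few per mill.

## Permutation constructions

*Edge switching* draws a source from the multiset of observed sources and,
independently, a target from the observed target multiset — both marginal
frequencies are preserved in expectation while the matching is destroyed.
*Network-uniform* sampling draws unique unordered node pairs uniformly.
Permuted TF pair sets (for the target-multiplicity question) and
length-matched permuted shortest-path sets (drawn without replacement to
match the real path-length multiset exactly) are built on top.  Sub-seeds
derive from (master seed, operation label, replicate index) via
`numpy.random.SeedSequence`, so streams never collide and every draw is
reproducible.

The TF target-multiplicity statistic is operationalized as the number of
sources with ≥ 2 distinct targets; because edge switching preserves the
source multiset, this statistic is largely conserved under the null and
the test has little power at small scale — the raw per-source
target-count vectors are exposed so alternative readings cost one line.

## Enrichment battery

* **Binomial cis enrichment** — under the null, the number of source
  genes whose best eSNP also shows a nominal (p < α) cis association is
  Binomial(n sources, α).  The tail is the *strict* P(X > k): an
  enumeration oracle confirms that this convention reproduces the
  reference value 3.6×10⁻¹⁵ at (k=50, n=286, α=0.05), whereas the
  inclusive tail gives ≈1.5×10⁻¹⁴.
* **Fisher 2×2 tests** (cis background, cluster co-occurrence, binding
  membership, exon-bin position) default to the one-sided enrichment
  alternative — every such comparison asks a directional question — with
  two-sided available by flag.
* **Gene-set enrichment** is the upper-tail hypergeometric with
  Benjamini–Hochberg FDR across tested categories; categories below a
  minimum overlap (default 2) are excluded *before* testing.  A TF
  "unit" (source plus its targets) counts as enriched when any category
  reaches q ≤ 0.05.
* **Co-expression** compares |Spearman r| of source–target pairs against
  all gene pairs in the expression matrix (two-sided rank-sum);
  **effect-size** comparisons are one-sided rank-sums on |β|.  Rank-sum
  tests use the exact distribution for small tie-free samples and the
  normal approximation otherwise.
* **Path-content comparison** counts, per category, member genes along
  the real shortest paths (with repetition across paths) and the number
  of paths containing ≥ 1 member, each against length-matched permuted
  path sets; ties count toward the empirical p ("equal or greater").
  Endpoints are included by default; an endpoints-excluded variant is a
  flag.
* **Positional bias**: exonic eSNPs versus background exonic SNPs, (i)
  middle-exon versus first/last bins (strand-aware exon order;
  single-exon genes excluded, two-exon genes contribute only edge bins)
  and (ii) strand-aware fractional position along the concatenated exons
  (one-sided rank-sum, "farther down the transcript").

Discrete exact tests are conservative under the null (their p-values are
super-uniform, not uniform); the calibration suite asserts KS-uniformity
only for the near-continuous statistics and P(p ≤ α) ≤ α for the discrete
ones.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical regime the analysis assumes, at
desk scale: ~50 samples, biallelic SNPs with dosage ~ Binomial(2, MAF),
MAF ~ U(0.1, 0.45), 2% missing calls, 200 genes with exon structure over 5
chromosomes (intergenic gaps straddling the 1 Mb cutoff so both local and
distal same-chromosome configurations occur), and a 4-community
planted-partition PPI graph.  Default densities p_in = 0.12,
p_out = 0.006 give mean degree ≈ 7 — the mean degree of a curated human
PPI network at this scale; denser settings make every node pair distance
≈ 2 and erase the proximity phenomenon being studied.

Planted effects follow the two-mode mechanism: an eSNP shifts its host
(source) gene in cis (source = β_cis·dosage + noise), and each target
follows the realized source level (target = β_trans·source + noise).
Exon sources take one target within 2 hops, sampled with weight
degree³ (hub-biased) and across community boundaries when possible; TF
sources take 3 targets from their own community (a "unit").  Sources and
targets are globally disjoint, exon sources are non-TF genes, and TF
sources are planted on intronic SNPs — without this separation, chained
effects and cross-scan leakage create strong associations with no defined
ground truth.  The planted SNP is the source's highest-MAF eligible SNP,
the detectability-maximizing choice a power-conscious simulation makes at
n = 50.  Defaults: β_cis = β_trans = 1.5, noise SD 1, 30 exon sources, 6
TF units.

Not emulated: linkage disequilibrium, population structure, read-level
counts or normalization artifacts (expression is generated directly on a
normalized scale), allele-specific expression, and heavy-tailed PPI
degree distributions.  Passing tests therefore demonstrate correctness of
the machinery and recoverability of planted signal under this idealized
regime, not performance on real cohorts.

### Analysis thresholds on the planted fixture

The strict reporting threshold is p ≤ 10⁻⁶.  The trend, unit, and
co-occurrence analyses use a *candidate domain* of p ≤ 10⁻³, chosen so
that the expected number of chance associations (~54,000 tests × 10⁻³)
is the same order as the planted pairs: the threshold-trend diagnostic
exists precisely because true positives are progressively diluted by
false positives as the threshold loosens, so the domain must mix the two.
This mirrors how the original analysis placed its domain just below the
point where true associations emerge for its own (much larger) testing
burden.

### Power at the strict threshold

With target = β_trans·(source) + noise, the SNP→target correlation is
bounded by ρ = βcβtV / √(V·(βt²(βc²V+σ²)+σ²)) ≤ 0.66 for β = 1.5, σ = 1
even at MAF → 0.5 (V = dosage variance).  At n = 50 this gives per-pair
power ≈ 0.6–0.7 at p < 10⁻⁶, so roughly half to two-thirds of planted
exon pairs are recovered at the strict threshold — an intrinsic property
of the stated effect sizes and sample size, not of the implementation.
The candidate domain recovers most of the remainder.

## Numerical conventions

* Missing dosage sentinel −1 (int8), distinct from any dosage; expression
  generation mean-imputes missing calls of planted SNPs (generation only —
  analysis always drops them pairwise).
* p = 0 from a perfect fit is floored at 10⁻³⁰⁰ before −log10 in trend
  thresholds.
* Zero-variance trend curves report r = 0 with a `degenerate` flag rather
  than NaN.
* Ties everywhere break lexicographically (best eSNP per pair, geodesic
  predecessors, cluster renumbering by size then smallest member).

## Known limitations

* The Louvain step is a heuristic; partitions are seeded and reproducible
  but not guaranteed optimal.
* The trend permutation null with `network_uniform` pairs treats the pair
  set as exchangeable; it does not condition on the real degree sequence
  (the edge-switching scheme partially does).
* `sample_network_pairs` uses rejection sampling; requesting nearly all
  possible pairs of a small graph is slow (bounded by a feasibility
  check).
* The binding-pair and gene-set fixtures are synthetic stand-ins keyed to
  the planted structure; no real database content ships with the package.
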