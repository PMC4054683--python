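# transppi

Trans-acting genetic variants projected onto a protein–protein
interaction (PPI) network: association scanning, topological profiling
against permutation nulls, modularity clustering, and an enrichment
battery — with a synthetic-data generator that plants known cis→trans
effects so the whole chain is verifiable end to end.

## The scientific problem

Expression SNPs (eSNPs) associated with *distal* transcripts — on another
chromosome, or ≥ 1 Mb away — are hard to interpret: the multiple-testing
burden is crushing and the mechanism is rarely obvious.  Two classes of
variants are natural suspects, because they sit in regions with known
regulatory potential *and* map onto a PPI network: SNPs in **exons**
(which can act through a mild cis effect on their host gene, the
"source", that propagates to a trans "target") and SNPs in the spans of
**transcription factors** (which can regulate whole sets of targets).

For each trans pair the package asks where source and target sit on the
PPI network.  The diagnostic signatures, for a candidate list sorted by
association strength:

* **exon sources** — the stronger the association, the *shorter* the
  source–target network distance and the *higher* the target's degree.
  Cumulative averages of each property across significance prefixes are
  summarized by Spearman's r against −log10 p and tested against
  permuted source–target pair sets;
* **TF sources** — a TF and its targets form a "unit" that tends to be
  functionally coherent: enriched for gene-set categories
  (hypergeometric + Benjamini–Hochberg FDR) and concentrated in a single
  modularity (Louvain) cluster of the network (Fisher exact test versus
  permuted pairs).

Supporting statistics: the binomial test for excess nominal cis effects
among source genes (P(X > k), X ~ Bin(n sources, α)); Fisher tests
against genome-wide backgrounds; co-expression (|Spearman r|) of pairs
versus all gene pairs; positional bias of eSNPs within transcripts; and
content comparison of real versus length-matched permuted shortest paths.
Network distance is the shortest-path hop count, with disconnected pairs
assigned twice the maximum finite distance.

It is a library first (`import transppi`), with a thin `transppi` CLI
(`simulate`, `associate`, `topology`, `cluster`, `scan`, `enrich`,
`run-all`) over the same functions.

## Worked example

Simulate the standard planted study (50 samples, 200 genes, 4-community
PPI network, 30 planted exon source–target pairs and 6 TF units), scan
exonic SNPs for trans associations, and profile the topological trends:

```python
import transppi as tp
from transppi.trends import cumulative_property_profile

data = tp.standard_planted_dataset(seed=1)
geno = tp.filter_genotypes(data.genotypes)
expr = data.expression.align_samples(geno.samples)

pairs = tp.scan_trans(geno, expr, data.annotation, "exonic", 1e-3)
best = tp.best_esnp_per_pair(pairs)
print(f"{len(best)} candidate exon source-target pairs")

dm = tp.all_pairs_distances(data.network)
profile = cumulative_property_profile(best, dm, data.network, p_max=1e-3)
nulls = tp.permuted_trend_distribution(best, data.network, dm,
                                       n_perm=1000, seed=17, p_max=1e-3)
for name, res in tp.trend_significance(profile, nulls).items():
    print(f"{name:14s} r = {res['r']:+.3f}   empirical p = {res['empirical_p']:.3f}")

planted = set(data.plan.pairs(kind="exon"))
found = {(r.source_gene, r.target_gene) for r in best}
print(f"planted pairs in candidate set: {len(planted & found)}/{len(planted)}")
```

prints

```
91 candidate exon source-target pairs
distance       r = -0.993   empirical p = 0.000
source_degree  r = -0.739   empirical p = 0.905
target_degree  r = +0.992   empirical p = 0.000
planted pairs in candidate set: 28/30
```

Read: as the significance threshold loosens, the cumulative mean
source–target distance rises (r = −0.99 against −log10 p) and the mean
target degree falls (r = +0.99) — the planted proximal, hub-directed
pairs dominate the most significant prefixes and chance pairs dilute the
tail.  Fewer than 1 permuted pair set in 1000 produces a trend that
strong, hence empirical p below 0.001.  Source degree carries no planted
signal, and correctly shows none.  The same dataset and every downstream
table can be produced from the shell with
`transppi run-all --seed 1 --out-dir run1`.

The methods note in `docs/methods.md` documents the models, conventions,
and the generator's scope.

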