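"""The statistical battery: exact tests, enrichment, comparisons.

All background-comparison enrichments default to the one-sided
(enrichment-direction) alternative, since each asks whether a phenomenon is
over-represented; two-sided variants are available by flag.  Exact tests
(Fisher, hypergeometric, binomial) delegate to scipy's exact routines and
are validated against full-enumeration oracles in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    EnrichmentResult, ExpressionMatrix, GeneAnnotation, GeneSetCollection,
    RandomPairSet, SourceTargetPair, Unit, annotation_index,
)
from .errors import FeasibilityError, InvalidParameterError
from .network import ClusterPartition, PathRecord

log = logging.getLogger(__name__)

__all__ = [
    "fisher_2x2", "binomial_cis_enrichment", "benjamini_hochberg",
    "hypergeometric_enrichment", "unit_enrichment", "coexpression_comparison",
    "effect_size_comparison", "cluster_cooccurrence",
    "binding_membership_enrichment", "path_category_enrichment",
    "positional_bias_test",
]


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

def fisher_2x2(a: int, b: int, c: int, d: int,
               sided: str = "greater") -> tuple[float, float]:
    """Fisher's exact test on the table [[a, b], [c, d]].

    ``sided='greater'`` tests over-representation of the a-cell (upper
    hypergeometric tail); ``'two'`` is the standard two-sided exact test.
    Returns (odds ratio, p).
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise InvalidParameterError("counts must be non-negative integers")
    if sided not in ("greater", "two"):
        raise InvalidParameterError("sided must be 'greater' or 'two'")
    alternative = "greater" if sided == "greater" else "two-sided"
    res = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def binomial_cis_enrichment(k_nominal: int, n_sources: int,
                            alpha: float = 0.05) -> float:
    """Upper tail P(X > k) under Binomial(n_sources, alpha).

    Under the null, the number of source genes whose best eSNP also shows a
    nominal (p < alpha) cis association is Binomial(n, alpha).  The strict
    tail P(X > k) is used: it reproduces the printed reference value at
    (k=50, n=286, alpha=0.05) where the inclusive tail does not.
    """
    if not (0 <= k_nominal <= n_sources):
        raise InvalidParameterError("need 0 <= k <= n")
    if not (0 < alpha < 1):
        raise InvalidParameterError("alpha must be in (0, 1)")
    return float(stats.binom.sf(k_nominal, n_sources, alpha))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------------

def hypergeometric_enrichment(query: set[str], collection: GeneSetCollection,
                              min_overlap: int = 1,
                              ) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of a query set per category.

    Categories overlapping the query below ``min_overlap`` are excluded
    before testing; BH q-values are computed across the tested categories.
    Results are sorted by ascending p (ties by category name).
    """
    if not collection.background:
        raise InvalidParameterError("empty background universe")
    stray = query - collection.background
    if stray:
        raise InvalidParameterError(
            f"query genes outside background: {sorted(stray)[:5]}")
    M = len(collection.background)
    N = len(query)
    rows = []
    for name in sorted(collection.categories):
        members = collection.categories[name]
        K = len(members)
        k = len(query & members)
        if k < min_overlap:
            continue
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        rows.append((name, k, K, p))
    if not rows:
        return []
    qvals = benjamini_hochberg([p for (_, _, _, p) in rows])
    out = [EnrichmentResult(category=name, overlap=k, set_size=K, query_size=N,
                            background_size=M, p=p, q=float(q))
           for (name, k, K, p), q in zip(rows, qvals)]
    out.sort(key=lambda r: (r.p, r.category))
    return out


def unit_enrichment(units: Sequence[Unit], collection: GeneSetCollection,
                    min_overlap: int = 2, fdr_threshold: float = 0.05,
                    ) -> dict[str, object]:
    """Functional enrichment of each TF unit (source plus targets).

    Units with fewer than two genes in total are skipped.  A unit counts as
    enriched when any category reaches q <= ``fdr_threshold`` with at least
    ``min_overlap`` annotated genes.
    """
    per_unit: dict[str, list[EnrichmentResult]] = {}
    n_considered = 0
    n_enriched = 0
    for unit in units:
        genes = set(unit.genes) & collection.background
        if len(unit.genes) < 2:
            continue
        n_considered += 1
        results = hypergeometric_enrichment(genes, collection,
                                            min_overlap=min_overlap)
        per_unit[unit.tf_source] = results
        if any(r.q <= fdr_threshold for r in results):
            n_enriched += 1
    return {"per_unit": per_unit, "n_considered": n_considered,
            "n_enriched": n_enriched}


# ---------------------------------------------------------------------------
# expression comparisons
# ---------------------------------------------------------------------------

def _abs_spearman_matrix(E: ExpressionMatrix) -> np.ndarray:
    """|Spearman r| for all gene pairs (genes x genes, diagonal 1)."""
    ranks = stats.rankdata(E.values, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns give NaN, kept as NaN
        corr = np.corrcoef(ranks, rowvar=False)
    return np.abs(corr)


def coexpression_comparison(pairs: Sequence[SourceTargetPair] | Sequence[tuple[str, str]],
                            E: ExpressionMatrix) -> dict[str, float]:
    """Are source-target pairs more co-expressed than arbitrary gene pairs?

    Computes |Spearman r| for every source-target pair and for the full
    background of gene pairs in the expression matrix, then compares the two
    distributions with a two-sided Wilcoxon rank-sum test.
    """
    pair_list = [(r.source_gene, r.target_gene) if isinstance(r, SourceTargetPair)
                 else (r[0], r[1]) for r in pairs]
    if not pair_list:
        raise InvalidParameterError("no source-target pairs given")
    mat = _abs_spearman_matrix(E)
    gpos = {g: i for i, g in enumerate(E.genes)}
    real = []
    for (s, t) in pair_list:
        if s in gpos and t in gpos:
            real.append(mat[gpos[s], gpos[t]])
    if not real:
        raise InvalidParameterError("no pairs with both genes in the expression matrix")
    iu = np.triu_indices(len(E.genes), k=1)
    background = mat[iu]
    background = background[~np.isnan(background)]
    if background.size < 2:
        raise InvalidParameterError("background needs at least 2 gene pairs")
    real_arr = np.asarray(real)
    p = float(stats.mannwhitneyu(real_arr, background,
                             alternative="two-sided").pvalue)
    return {
        "wilcoxon_p": p,
        "median_abs_r_real": float(np.median(real_arr)),
        "median_abs_r_background": float(np.median(background)),
        "n_real": int(real_arr.size),
        "n_background": int(background.size),
    }


def effect_size_comparison(trans_betas: Sequence[float],
                           cis_betas: Sequence[float]) -> float:
    """One-sided Wilcoxon rank-sum p for |trans betas| exceeding |cis betas|.

    Exact for small tie-free samples, normal approximation otherwise.
    """
    a = np.abs(np.asarray(trans_betas, dtype=float))
    b = np.abs(np.asarray(cis_betas, dtype=float))
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both effect-size lists must be non-empty")
    return float(stats.mannwhitneyu(a, b, alternative="greater",
                                    method="auto").pvalue)


# ---------------------------------------------------------------------------
# cluster and database comparisons
# ---------------------------------------------------------------------------

def cluster_cooccurrence(pairs: Sequence[SourceTargetPair] | Sequence[tuple[str, str]],
                         partition: ClusterPartition,
                         null_pairs: RandomPairSet) -> dict[str, float]:
    """Do source and target share a PPI cluster more often than random pairs?

    Counts same-cluster pairs among the real list and among the permuted
    list, then applies a one-sided Fisher exact test for enrichment.
    """
    def _same(s: str, t: str) -> bool:
        return partition.same_cluster(s, t)

    pair_list = [(r.source_gene, r.target_gene) if isinstance(r, SourceTargetPair)
                 else (r[0], r[1]) for r in pairs]
    if not pair_list:
        raise InvalidParameterError("no real pairs given")
    real_k = sum(_same(s, t) for (s, t) in pair_list)
    real_n = len(pair_list)
    null_k = sum(_same(s, t) for (s, t) in null_pairs.pairs)
    null_n = len(null_pairs.pairs)
    _, p = fisher_2x2(real_k, real_n - real_k, null_k, null_n - null_k,
                      sided="greater")
    return {"real_k": real_k, "real_n": real_n, "null_k": null_k,
            "null_n": null_n, "fisher_p": p}


def binding_membership_enrichment(real_tf_pairs: Sequence[tuple[str, str]],
                                  null_tf_pairs: Sequence[tuple[str, str]],
                                  binding_db: Sequence[tuple[str, str]],
                                  ) -> dict[str, float]:
    """Are real TF->target pairs over-represented in a binding database?

    Both pair lists are first restricted to pairs whose TF appears in the
    database at all; exact (TF, target) membership is then compared by a
    one-sided Fisher test.
    """
    db = {(s, t) for (s, t) in binding_db}
    if not db:
        raise FeasibilityError("binding database is empty")
    db_tfs = {s for (s, _) in db}

    def _counts(pair_list: Sequence[tuple[str, str]]) -> tuple[int, int]:
        eligible = [(s, t) for (s, t) in pair_list if s in db_tfs]
        hits = sum((s, t) in db for (s, t) in eligible)
        return hits, len(eligible)

    real_hit, real_n = _counts(real_tf_pairs)
    null_hit, null_n = _counts(null_tf_pairs)
    if real_n == 0 or null_n == 0:
        raise FeasibilityError("no pairs with a database-covered TF source")
    _, p = fisher_2x2(real_hit, real_n - real_hit, null_hit, null_n - null_hit,
                      sided="greater")
    return {"real_in_db": real_hit, "real_eligible": real_n,
            "null_in_db": null_hit, "null_eligible": null_n, "fisher_p": p}


# ---------------------------------------------------------------------------
# path-content comparison
# ---------------------------------------------------------------------------

def _path_category_stats(paths: Sequence[PathRecord], members: set[str],
                         include_endpoints: bool) -> tuple[int, int]:
    gene_count = 0
    path_count = 0
    for p in paths:
        genes = p.nodes if include_endpoints else p.intermediates
        hits = sum(g in members for g in genes)
        gene_count += hits           # with repetition across paths
        path_count += hits > 0
    return gene_count, path_count


def path_category_enrichment(real_paths: Sequence[PathRecord],
                             permuted_sets: Sequence[Sequence[PathRecord]],
                             collection: GeneSetCollection,
                             include_endpoints: bool = True,
                             ) -> dict[str, dict[str, float]]:
    """Two empirical statistics per category over shortest-path contents.

    For each category: (i) how many member genes appear along the real
    paths, counted with repetition across paths; (ii) how many real paths
    contain at least one member gene.  Each statistic's empirical p is the
    fraction of length-matched permuted path sets achieving an equal or
    greater value (ties count toward p).  Categories with no gene in the
    background are skipped with a warning.
    """
    if not permuted_sets:
        raise InvalidParameterError("need at least one permuted path set")
    out: dict[str, dict[str, float]] = {}
    for name in sorted(collection.categories):
        members = collection.categories[name] & collection.background
        if not members:
            warnings.warn(f"category {name} absent from background; skipped",
                          stacklevel=2)
            continue
        real_g, real_p = _path_category_stats(real_paths, members, include_endpoints)
        perm = np.array([_path_category_stats(ps, members, include_endpoints)
                         for ps in permuted_sets])
        out[name] = {
            "gene_count": real_g,
            "path_count": real_p,
            "gene_count_emp_p": float((perm[:, 0] >= real_g).mean()),
            "path_count_emp_p": float((perm[:, 1] >= real_p).mean()),
        }
    return out


# ---------------------------------------------------------------------------
# positional bias of exonic eSNPs
# ---------------------------------------------------------------------------

def _exon_bin(gene: GeneAnnotation, position: int) -> str | None:
    """'first' / 'middle' / 'last' exon bin, strand-aware; None if not binnable.

    Single-exon genes are excluded; in two-exon genes only first/last bins
    exist.  Exon order follows transcription: on the minus strand the
    highest-coordinate exon is first.
    """
    m = len(gene.exons)
    if m < 2:
        return None
    idx = None
    for i, (s, e) in enumerate(gene.exons):
        if s <= position <= e:
            idx = i
            break
    if idx is None:
        return None
    if gene.strand == "-":
        idx = m - 1 - idx
    if idx == 0:
        return "first"
    if idx == m - 1:
        return "last"
    return "middle"


def _transcript_fraction(gene: GeneAnnotation, position: int) -> float | None:
    """Strand-aware fractional position within the concatenated exons."""
    offset = 0
    found = None
    for (s, e) in gene.exons:
        if s <= position <= e:
            found = offset + (position - s)
            break
        offset += e - s + 1
    if found is None:
        return None
    total = gene.exonic_length
    if gene.strand == "-":
        found = total - 1 - found
    return found / total if total > 1 else 0.0


def positional_bias_test(esnp_positions: Sequence[tuple[str, int]],
                         all_snp_positions: Sequence[tuple[str, int]],
                         annotation: Sequence[GeneAnnotation]) -> dict[str, float]:
    """Positional bias of exonic eSNPs relative to background exonic SNPs.

    Tests (i) over-representation of eSNPs in middle exons versus first/last
    exons (one-sided Fisher; genes need at least three exons to contribute a
    middle bin) and (ii) whether eSNPs lie farther down the transcript
    (one-sided rank-sum on strand-aware fractional positions).  Inputs are
    (gene_id, position) records of exonic SNPs.
    """
    ann = annotation_index(annotation)

    def _bins(records: Sequence[tuple[str, int]]) -> tuple[int, int, list[float]]:
        middle = edge = 0
        fracs: list[float] = []
        for gene_id, pos in records:
            gene = ann.get(gene_id)
            if gene is None:
                continue
            b = _exon_bin(gene, pos)
            if b == "middle":
                middle += 1
            elif b in ("first", "last"):
                edge += 1
            f = _transcript_fraction(gene, pos)
            if f is not None:
                fracs.append(f)
        return middle, edge, fracs

    e_mid, e_edge, e_frac = _bins(esnp_positions)
    b_mid, b_edge, b_frac = _bins(all_snp_positions)
    if e_mid + e_edge == 0 or b_mid + b_edge == 0:
        raise InvalidParameterError("no binnable exonic SNPs in one of the inputs")
    _, fisher_p = fisher_2x2(e_mid, e_edge, b_mid, b_edge, sided="greater")
    if not e_frac or len(b_frac) < 2:
        raise InvalidParameterError("too few transcript positions for the rank test")
    wilcoxon_p = float(stats.mannwhitneyu(e_frac, b_frac,
                                          alternative="greater").pvalue)
    return {
        "exon_bin_fisher_p": fisher_p,
        "transcript_position_wilcoxon_p": wilcoxon_p,
        "esnp_middle": e_mid, "esnp_edge": e_edge,
        "background_middle": b_mid, "background_edge": b_edge,
    }
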