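"""Genotype QC and linear-regression association scanning.

The association model is ordinary least squares of expression on additive
dosage (0/1/2 copies of the minor allele), with a two-sided t-test on the
slope at n-2 degrees of freedom.  Samples with a missing genotype call are
dropped pairwise per test.  A trans association requires the target gene to
sit on a different chromosome than the eSNP, or at least 1 Mb away on the
same chromosome (gap measured from the SNP position to the nearest target
span boundary).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy import stats

from .datatypes import (
    MISSING, AssociationStat, ExpressionMatrix, GeneAnnotation, GenotypeMatrix,
    SourceTargetPair, TRANS_DIFF_CHROM, TRANS_SAME_CHROM_FAR, annotation_index,
)
from .errors import (
    ConsistencyError, InsufficientDataError, InvalidParameterError, UndefinedTestError,
)

log = logging.getLogger(__name__)

TRANS_MIN_GAP_BP = 1_000_000

REGION_ALIASES = {
    "exonic": "exonic", "exon": "exonic",
    "tf_span": "tf_span", "tf": "tf_span",
}


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def filter_genotypes(G: GenotypeMatrix,
                     maf_min: float = 0.05,
                     snp_missing_max: float = 0.1,
                     sample_missing_max: float = 0.1) -> GenotypeMatrix:
    """Standard genotype QC with strict inequalities.

    SNPs are filtered first (MAF strictly above ``maf_min`` and missingness
    strictly below ``snp_missing_max``); samples are then filtered on their
    missingness over the retained SNPs (strictly below ``sample_missing_max``).
    """
    if G.n_snps == 0 or G.n_samples == 0:
        raise InvalidParameterError("genotype matrix is empty")
    maf = G.maf()
    snp_keep = (maf > maf_min) & (G.snp_missingness() < snp_missing_max)
    # NaN MAF (all calls missing) fails the comparison and is dropped.
    snp_keep &= ~np.isnan(maf)
    after_snps = G.subset(snp_mask=snp_keep)
    if after_snps.n_snps == 0:
        log.warning("all %d SNPs removed by QC filters", G.n_snps)
        return after_snps
    sample_keep = after_snps.sample_missingness() < sample_missing_max
    out = after_snps.subset(sample_mask=sample_keep)
    log.info("QC: %d/%d SNPs and %d/%d samples retained",
             out.n_snps, G.n_snps, out.n_samples, G.n_samples)
    return out


# ---------------------------------------------------------------------------
# single association test
# ---------------------------------------------------------------------------

def _ols_stats(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Slope, SE, t and two-sided p of OLS of each column of Y on x.

    ``x`` is a clean 1-D regressor with variance > 0; ``Y`` has one column
    per response.  Shared by the scalar test and the vectorized scan so the
    two routes are numerically identical.
    """
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    Yc = Y - Y.mean(axis=0)
    sxy = xc @ Yc
    beta = sxy / sxx
    syy = (Yc * Yc).sum(axis=0)
    rss = np.maximum(syy - beta * sxy, 0.0)
    dof = n - 2
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf * np.sign(beta))
    t = np.where((se == 0) & (beta == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, se, t, p


def test_association(dosages: Sequence[float], expression: Sequence[float]) -> AssociationStat:
    """OLS association of one expression vector on one dosage vector.

    Missing dosages (sentinel or NaN) are dropped pairwise.  Raises
    :class:`InsufficientDataError` below 3 complete observations and
    :class:`UndefinedTestError` for a monomorphic (zero-variance) dosage.
    """
    x = np.asarray(dosages, dtype=float)
    y = np.asarray(expression, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("dosage and expression vectors must align")
    keep = (x != MISSING) & ~np.isnan(x) & ~np.isnan(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"only {n} complete observations (need >= 3)")
    if np.ptp(x) == 0:
        raise UndefinedTestError("zero dosage variance: association undefined")
    beta, se, t, p = _ols_stats(x, y[:, None])
    return AssociationStat(beta=float(beta[0]), se=float(se[0]),
                           t=float(t[0]), p=float(p[0]), n_used=int(n))


# ---------------------------------------------------------------------------
# trans classification
# ---------------------------------------------------------------------------

def trans_relation(snp_chrom: str, snp_pos: int, target: GeneAnnotation) -> str | None:
    """Classify a SNP-target pair as trans, or None when local (cis-range).

    The same-chromosome gap is from the SNP position to the nearest target
    span boundary; a gap of at least 1 Mb qualifies as trans.
    """
    if snp_chrom != target.chromosome:
        return TRANS_DIFF_CHROM
    if snp_pos < target.start:
        gap = target.start - snp_pos
    elif snp_pos > target.end:
        gap = snp_pos - target.end
    else:
        gap = 0
    return TRANS_SAME_CHROM_FAR if gap >= TRANS_MIN_GAP_BP else None


# ---------------------------------------------------------------------------
# genome-wide trans scan
# ---------------------------------------------------------------------------

def scan_trans(G: GenotypeMatrix, E: ExpressionMatrix,
               annotation: Sequence[GeneAnnotation],
               region_class: str, p_threshold: float) -> list[SourceTargetPair]:
    """Test every region-class SNP against every annotated transcript.

    Keeps pairs with p <= ``p_threshold`` that satisfy the trans relation,
    excluding the SNP's own host gene.  Output order is deterministic
    (ascending p, then SNP id, then target id) and independent of input
    ordering.
    """
    region = REGION_ALIASES.get(region_class)
    if region is None:
        raise InvalidParameterError(
            f"unknown region class {region_class!r}; use 'exonic' or 'tf_span'")
    if not (0 < p_threshold <= 1):
        raise InvalidParameterError("p_threshold must be in (0, 1]")
    if G.samples != E.samples:
        raise ConsistencyError("genotype and expression sample orders differ; align first")

    ann = annotation_index(annotation)
    genes = [g for g in E.genes if g in ann]
    if len(genes) < len(E.genes):
        log.warning("%d expression genes lack annotation and are skipped",
                    len(E.genes) - len(genes))
    gene_cols = np.array([E.genes.index(g) for g in genes])
    gene_chrom = np.array([ann[g].chromosome for g in genes])
    gene_start = np.array([ann[g].start for g in genes])
    gene_end = np.array([ann[g].end for g in genes])

    snp_mask = G.snp_meta[region].to_numpy(dtype=bool)
    results: list[SourceTargetPair] = []
    for j in np.nonzero(snp_mask)[0]:
        meta = G.snp_meta.iloc[j]
        x = G.dosages[:, j].astype(float)
        keep = x != MISSING
        n = int(keep.sum())
        if n < 3:
            continue
        xk = x[keep]
        if np.ptp(xk) == 0:
            continue
        beta, se, t, p = _ols_stats(xk, E.values[np.ix_(keep, gene_cols)])
        hit = np.nonzero(p <= p_threshold)[0]
        for k in hit:
            gene = genes[k]
            if gene == meta["source_gene"]:
                continue
            relation = trans_relation(meta["chromosome"], int(meta["position"]), ann[gene])
            if relation is None:
                continue
            results.append(SourceTargetPair(
                esnp_id=str(G.snp_meta.index[j]),
                source_gene=str(meta["source_gene"]),
                target_gene=gene,
                assoc=AssociationStat(beta=float(beta[k]), se=float(se[k]),
                                      t=float(t[k]), p=float(p[k]), n_used=n),
                relation=relation,
            ))
    results.sort(key=lambda r: (r.assoc.p, r.esnp_id, r.target_gene))
    return results


def cis_effect_test(pair: SourceTargetPair, G: GenotypeMatrix,
                    E: ExpressionMatrix) -> float:
    """P-value of the pair's eSNP against its own source gene's expression."""
    dosage = G.dosage_vector(pair.esnp_id)
    return test_association(dosage, E.gene_vector(pair.source_gene)).p


def best_esnp_per_pair(pairs: Sequence[SourceTargetPair]) -> list[SourceTargetPair]:
    """One record per unique (source, target): minimal p, ties by SNP id."""
    if not pairs:
        raise InvalidParameterError("no pairs given")
    best: dict[tuple[str, str], SourceTargetPair] = {}
    for r in pairs:
        key = (r.source_gene, r.target_gene)
        cur = best.get(key)
        if cur is None or (r.assoc.p, r.esnp_id) < (cur.assoc.p, cur.esnp_id):
            best[key] = r
    out = list(best.values())
    out.sort(key=lambda r: (r.assoc.p, r.esnp_id, r.target_gene))
    return out


def pair_summary(pairs: Sequence[SourceTargetPair]) -> dict[str, float]:
    """Bookkeeping counts over a pair list (records, unique entities, relations)."""
    n = len(pairs)
    uniq_pairs = {(r.source_gene, r.target_gene) for r in pairs}
    n_diff = sum(r.relation == TRANS_DIFF_CHROM for r in pairs)
    n_far = sum(r.relation == TRANS_SAME_CHROM_FAR for r in pairs)
    return {
        "n_records": n,
        "n_unique_pairs": len(uniq_pairs),
        "n_unique_esnps": len({r.esnp_id for r in pairs}),
        "n_unique_sources": len({r.source_gene for r in pairs}),
        "n_unique_targets": len({r.target_gene for r in pairs}),
        "n_diff_chrom": n_diff,
        "n_same_chrom_far": n_far,
        "pct_diff_chrom": 100.0 * n_diff / n if n else float("nan"),
        "pct_same_chrom_far": 100.0 * n_far / n if n else float("nan"),
    }
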