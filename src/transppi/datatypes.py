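"""Core data containers shared across the pipeline.

Conventions used throughout the package:

* Genomic coordinates are 1-based and intervals are closed on both ends.
  A SNP whose position equals an exon boundary base is exonic.
* Genotypes are additive dosages in {0, 1, 2}; missing calls are stored as
  the sentinel :data:`MISSING` (-1), which is distinct from any dosage.
* Expression values are on an already-normalized continuous scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InvalidParameterError

#: Sentinel for a missing genotype call (distinct from any dosage 0/1/2).
MISSING: int = -1


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """A gene span with its exon structure.

    ``exons`` are (start, end) pairs in 1-based closed coordinates, sorted
    by start, non-overlapping, and contained in [start, end].  ``is_tf``
    marks genes coding for transcription factors; for those, SNPs anywhere
    in the span (introns included) count as TF-region SNPs.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InvalidParameterError(
                f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise InvalidParameterError(
                f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        prev_end = None
        for (s, e) in self.exons:
            if s > e:
                raise InvalidParameterError(
                    f"{self.gene_id}: exon ({s},{e}) has start > end")
            if s < self.start or e > self.end:
                raise InvalidParameterError(
                    f"{self.gene_id}: exon ({s},{e}) outside gene span")
            if prev_end is not None and s <= prev_end:
                raise InvalidParameterError(
                    f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def in_exon(self, position: int) -> bool:
        """True when ``position`` falls inside an exon (closed intervals)."""
        return any(s <= position <= e for (s, e) in self.exons)

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for (s, e) in self.exons)


def annotation_index(annotation: Sequence[GeneAnnotation]) -> dict[str, GeneAnnotation]:
    """Index by gene id, enforcing uniqueness."""
    idx: dict[str, GeneAnnotation] = {}
    for gene in annotation:
        if gene.gene_id in idx:
            raise ConsistencyError(f"duplicate gene id {gene.gene_id}")
        idx[gene.gene_id] = gene
    return idx


# ---------------------------------------------------------------------------
# genotype / expression matrices
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Sample x SNP dosage matrix with per-SNP metadata.

    ``dosages`` is an int8 array of shape (n_samples, n_snps) holding
    0/1/2 or :data:`MISSING`.  ``snp_meta`` is indexed by SNP id and carries
    ``chromosome``, ``position``, ``source_gene`` (host gene id or empty),
    and the boolean region flags ``exonic`` and ``tf_span``.
    """

    samples: list[str]
    dosages: np.ndarray
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.snp_meta)):
            raise ConsistencyError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snp_meta)} SNPs")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ConsistencyError("dosages must be 0/1/2 or the missing sentinel")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_meta.index)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snp_meta)

    def dosage_vector(self, snp_id: str) -> np.ndarray:
        j = self.snp_meta.index.get_loc(snp_id)
        return self.dosages[:, j]

    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency from non-missing calls only."""
        observed = self.dosages != MISSING
        with np.errstate(invalid="ignore"):
            counts = np.where(observed, self.dosages, 0).sum(axis=0)
            n_obs = observed.sum(axis=0)
            freq = np.divide(counts, 2.0 * n_obs,
                             out=np.full(self.n_snps, np.nan), where=n_obs > 0)
        return np.minimum(freq, 1.0 - freq)

    def snp_missingness(self) -> np.ndarray:
        return (self.dosages == MISSING).mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        return (self.dosages == MISSING).mean(axis=1)

    def subset(self, sample_mask: np.ndarray | None = None,
               snp_mask: np.ndarray | None = None) -> "GenotypeMatrix":
        s = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask)
        v = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask)
        return GenotypeMatrix(
            samples=[x for x, keep in zip(self.samples, s) if keep],
            dosages=self.dosages[np.ix_(s, v)],
            snp_meta=self.snp_meta.loc[v].copy(),
        )


@dataclass
class ExpressionMatrix:
    """Sample x gene matrix of normalized expression values."""

    samples: list[str]
    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ConsistencyError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.genes)} genes")
        if not np.all(np.isfinite(self.values)):
            raise ConsistencyError("expression values must be finite")

    def gene_vector(self, gene: str) -> np.ndarray:
        try:
            j = self.genes.index(gene)
        except ValueError:
            raise ConsistencyError(f"gene {gene} not in expression matrix") from None
        return self.values[:, j]

    def align_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        """Reorder rows to the given sample order (all must be present)."""
        order = []
        pos = {s: i for i, s in enumerate(self.samples)}
        for s in samples:
            if s not in pos:
                raise ConsistencyError(f"sample {s} missing from expression matrix")
            order.append(pos[s])
        return ExpressionMatrix(list(samples), list(self.genes), self.values[order])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.genes)


# ---------------------------------------------------------------------------
# association results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationStat:
    """One simple-regression association test result."""

    beta: float
    se: float
    t: float
    p: float
    n_used: int


#: allowed trans relations between an eSNP and its target gene
TRANS_DIFF_CHROM = "trans_diff_chrom"
TRANS_SAME_CHROM_FAR = "trans_same_chrom_far"


@dataclass(frozen=True)
class SourceTargetPair:
    """One eSNP -> transcript trans association."""

    esnp_id: str
    source_gene: str
    target_gene: str
    assoc: AssociationStat
    relation: str

    def __post_init__(self) -> None:
        if self.target_gene == self.source_gene:
            raise ConsistencyError("target gene must differ from source gene")
        if self.relation not in (TRANS_DIFF_CHROM, TRANS_SAME_CHROM_FAR):
            raise InvalidParameterError(f"unknown relation {self.relation!r}")


# ---------------------------------------------------------------------------
# planted effects / gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlannedEffect:
    """One planted source: a SNP, its host gene, and its trans targets."""

    snp_id: str
    source_gene: str
    cis_beta: float
    targets: tuple[tuple[str, float], ...]
    kind: str  # "exon" or "tf"


@dataclass(frozen=True)
class EffectPlan:
    """The full set of planted cis->trans effects for one simulation."""

    entries: tuple[PlannedEffect, ...]
    seed: int

    def pairs(self, kind: str | None = None) -> list[tuple[str, str]]:
        """Planted (source_gene, target_gene) pairs, optionally by kind."""
        out = []
        for e in self.entries:
            if kind is not None and e.kind != kind:
                continue
            out.extend((e.source_gene, t) for (t, _) in e.targets)
        return out

    def source_genes(self, kind: str | None = None) -> list[str]:
        return [e.source_gene for e in self.entries
                if kind is None or e.kind == kind]


@dataclass
class GeneSetCollection:
    """Named gene categories over a common background universe."""

    categories: dict[str, set[str]]
    background: set[str]

    def __post_init__(self) -> None:
        for name, members in self.categories.items():
            extra = members - self.background
            if extra:
                raise ConsistencyError(
                    f"category {name} has genes outside background: {sorted(extra)[:5]}")


# ---------------------------------------------------------------------------
# statistics layer
# ---------------------------------------------------------------------------

@dataclass
class PermutationNull:
    """A permutation distribution of one statistic."""

    statistics: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.statistics = np.asarray(self.statistics, dtype=float)
        if self.statistics.ndim != 1 or self.statistics.size == 0:
            raise InvalidParameterError("null distribution must be a non-empty vector")

    @property
    def n_perm(self) -> int:
        return self.statistics.size


@dataclass
class TrendProfile:
    """Cumulative topological averages across significance prefixes."""

    thresholds: np.ndarray                 # -log10(p) of last pair in prefix
    n_pairs: np.ndarray                    # prefix sizes, strictly increasing
    cumulative_means: dict[str, np.ndarray]
    spearman_r: dict[str, float]
    degenerate: dict[str, bool]            # True when r undefined (zero variance)


@dataclass(frozen=True)
class EnrichmentResult:
    """One category's over-representation test."""

    category: str
    overlap: int
    set_size: int
    query_size: int
    background_size: int
    p: float
    q: float


@dataclass(frozen=True)
class Unit:
    """A TF source together with its trans target genes."""

    tf_source: str
    targets: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.targets) < 1:
            raise InvalidParameterError("a unit needs at least one target")
        if self.tf_source in self.targets:
            raise ConsistencyError("TF source cannot be one of its own targets")

    @property
    def genes(self) -> frozenset[str]:
        return self.targets | {self.tf_source}


@dataclass(frozen=True)
class RandomPairSet:
    """A sampled set of (source, target) node pairs."""

    pairs: tuple[tuple[str, str], ...]
    scheme: str
    seed: int
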