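"""Synthetic genotype-expression-network data with planted trans effects.

The generator emulates, at desk scale, a cohort of ~50 sequenced samples
with transcriptional profiles: biallelic SNPs in Hardy-Weinberg proportions
(dosage ~ Binomial(2, MAF), no linkage disequilibrium), genes with exon
structure spread over several chromosomes, a community-structured PPI graph
(planted-partition model), and a set of planted causal chains: an eSNP
inside a source gene shifts the source's expression in cis, and the target's
expression follows the source (a trans effect mediated through the source).

Two source categories mirror the two trans-regulation modes under study:

* exon sources — the planted target is network-proximal to the source
  (within a small hop radius), biased toward high-degree nodes, and by
  default chosen across community boundaries;
* TF sources — several targets per source, all drawn from the source's own
  planted community, forming a functional "unit".

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .association import trans_relation
from .datatypes import (
    MISSING, EffectPlan, ExpressionMatrix, GeneAnnotation, GeneSetCollection,
    GenotypeMatrix, PlannedEffect, annotation_index,
)
from .errors import ConsistencyError, FeasibilityError, InvalidParameterError
from .network import ClusterPartition, PPINetwork, modularity

log = logging.getLogger(__name__)

__all__ = [
    "generate_annotation", "generate_ppi_network", "generate_genotypes",
    "plant_effects", "generate_expression", "generate_gene_sets",
    "generate_binding_pairs", "partition_from_planted_blocks",
    "SimulatedDataset", "standard_planted_dataset",
]


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(n_genes: int,
                        n_chromosomes: int = 5,
                        tf_fraction: float = 0.1,
                        exon_count_range: tuple[int, int] = (3, 8),
                        seed: int = 0,
                        gene_length_range: tuple[int, int] = (6_000, 20_000),
                        intergenic_gap_range: tuple[int, int] = (400_000, 2_400_000),
                        ) -> list[GeneAnnotation]:
    """Genes with exon structure, round-robin over chromosomes.

    Spans never overlap; the intergenic gap is drawn per gene, straddling
    the 1 Mb trans cutoff so that same-chromosome neighbors realize both
    local (cis-range) and distal (trans-range) configurations.  Exactly
    floor(tf_fraction * n_genes) genes are flagged as TFs.
    """
    if n_genes < 2 or n_chromosomes < 1:
        raise InvalidParameterError("need n_genes >= 2 and n_chromosomes >= 1")
    if not (0 <= tf_fraction <= 1):
        raise InvalidParameterError("tf_fraction must be in [0, 1]")
    lo, hi = exon_count_range
    if lo < 1 or hi < lo:
        raise InvalidParameterError("bad exon_count_range")
    rng = np.random.default_rng(seed)
    n_tf = int(np.floor(tf_fraction * n_genes))
    tf_idx = set(rng.choice(n_genes, size=n_tf, replace=False).tolist())
    cursors = {c: 1 for c in range(n_chromosomes)}
    genes: list[GeneAnnotation] = []
    for i in range(n_genes):
        chrom_i = i % n_chromosomes
        chrom = f"chr{chrom_i + 1}"
        gap = int(rng.integers(*intergenic_gap_range))
        length = int(rng.integers(*gene_length_range))
        start = cursors[chrom_i] + gap
        end = start + length - 1
        cursors[chrom_i] = end
        k = int(rng.integers(lo, hi + 1))
        # one exon per equal-width chunk of the span keeps them sorted/disjoint
        bounds = np.linspace(start, end + 1, k + 1).astype(int)
        exons = []
        for j in range(k):
            c0, c1 = int(bounds[j]), int(bounds[j + 1]) - 1
            width = c1 - c0
            s = c0 + int(rng.integers(0, max(width // 2, 1)))
            e = s + int(rng.integers(max((c1 - s) // 3, 1), max(c1 - s, 1) + 1))
            exons.append((s, min(e, c1)))
        genes.append(GeneAnnotation(
            gene_id=f"G{i + 1:04d}", chromosome=chrom, start=start, end=end,
            strand="+" if rng.random() < 0.5 else "-",
            exons=tuple(exons), is_tf=i in tf_idx))
    return genes


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

def generate_ppi_network(n_nodes: int, n_clusters: int,
                         p_in: float, p_out: float, seed: int = 0,
                         gene_ids: Sequence[str] | None = None) -> PPINetwork:
    """Planted-partition graph with near-equal blocks, keyed to gene ids.

    Within-block edges appear with probability ``p_in``, cross-block edges
    with ``p_out`` (``p_in > p_out``).  Planted block labels are retained on
    the returned network for recovery checks.
    """
    for p in (p_in, p_out):
        if not (0 <= p <= 1):
            raise InvalidParameterError("edge probabilities must be in [0, 1]")
    if p_in <= p_out:
        raise InvalidParameterError("need p_in > p_out for planted communities")
    if n_nodes < 2 or n_clusters < 1 or n_clusters > n_nodes:
        raise InvalidParameterError("need 2 <= n_nodes and 1 <= n_clusters <= n_nodes")
    if gene_ids is not None and len(gene_ids) != n_nodes:
        raise InvalidParameterError("gene_ids length must equal n_nodes")
    base, extra = divmod(n_nodes, n_clusters)
    sizes = [base + (1 if b < extra else 0) for b in range(n_clusters)]
    probs = [[p_in if i == j else p_out for j in range(n_clusters)]
             for i in range(n_clusters)]
    g = nx.stochastic_block_model(sizes, probs, seed=int(seed))
    names = list(gene_ids) if gene_ids is not None else [
        f"N{i + 1:04d}" for i in range(n_nodes)]
    mapping = {i: names[i] for i in range(n_nodes)}
    blocks: dict[str, int] = {}
    node = 0
    for b, size in enumerate(sizes):
        for _ in range(size):
            blocks[names[node]] = b
            node += 1
    relabeled = nx.relabel_nodes(nx.Graph(g.edges), mapping)
    relabeled.add_nodes_from(names)
    return PPINetwork(graph=relabeled, planted_blocks=blocks)


def partition_from_planted_blocks(network: PPINetwork) -> ClusterPartition:
    """The ground-truth planted partition as a :class:`ClusterPartition`."""
    if network.planted_blocks is None:
        raise InvalidParameterError("network carries no planted block labels")
    q = modularity(network, network.planted_blocks)
    return ClusterPartition(assignment=dict(network.planted_blocks), modularity_q=q)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def generate_genotypes(n_samples: int,
                       annotation: Sequence[GeneAnnotation],
                       snps_per_gene: int = 3,
                       maf_range: tuple[float, float] = (0.1, 0.45),
                       missing_rate: float = 0.02,
                       seed: int = 0) -> GenotypeMatrix:
    """Hardy-Weinberg dosages for SNPs positioned inside gene spans.

    Each SNP draws its MAF uniformly from ``maf_range`` and its dosages as
    Binomial(2, MAF) independently per sample (no LD).  Missing calls are
    planted independently at ``missing_rate``.  Region flags: ``exonic``
    when the position falls inside an exon interval (closed intervals, so a
    boundary base is exonic); ``tf_span`` when the host gene is a TF.
    """
    if n_samples < 1 or snps_per_gene < 1:
        raise InvalidParameterError("counts must be positive")
    lo, hi = maf_range
    if not (0 < lo <= hi < 0.5):
        raise InvalidParameterError("maf_range must satisfy 0 < lo <= hi < 0.5")
    if not (0 <= missing_rate < 1):
        raise InvalidParameterError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    ids, meta_rows, cols = [], [], []
    for gene in annotation:
        span = gene.end - gene.start + 1
        k = min(snps_per_gene, span)
        positions = np.sort(rng.choice(span, size=k, replace=False)) + gene.start
        for j, pos in enumerate(positions):
            maf = float(rng.uniform(lo, hi))
            dosage = rng.binomial(2, maf, size=n_samples).astype(np.int8)
            if missing_rate > 0:
                dosage[rng.random(n_samples) < missing_rate] = MISSING
            ids.append(f"{gene.gene_id}_snp{j + 1}")
            meta_rows.append({
                "chromosome": gene.chromosome, "position": int(pos),
                "source_gene": gene.gene_id,
                "exonic": gene.in_exon(int(pos)), "tf_span": gene.is_tf,
                "maf_drawn": maf,
            })
            cols.append(dosage)
    meta = pd.DataFrame(meta_rows, index=pd.Index(ids, name="snp_id"))
    return GenotypeMatrix(samples=samples,
                          dosages=np.column_stack(cols), snp_meta=meta)


# ---------------------------------------------------------------------------
# planted effects
# ---------------------------------------------------------------------------

def _best_snp(G: GenotypeMatrix, gene_id: str, exonic_only: bool) -> str | None:
    """The gene's highest-MAF eligible SNP (power at small n), ties by id.

    TF sources (``exonic_only=False``) are planted on intronic SNPs only:
    TF-region eSNPs are mostly intronic in practice, and keeping the two
    planted source classes disjoint in region keeps each scan's signature
    interpretable.
    """
    meta = G.snp_meta
    mask = (meta["source_gene"] == gene_id).to_numpy()
    exonic = meta["exonic"].to_numpy()
    if exonic_only:
        mask &= exonic
    else:
        mask &= ~exonic
    if not mask.any():
        return None
    maf = pd.Series(G.maf(), index=meta.index)[mask]
    return str(maf.sort_index().sort_values(kind="stable", ascending=False).index[0])


def plant_effects(annotation: Sequence[GeneAnnotation],
                  network: PPINetwork,
                  genotypes: GenotypeMatrix,
                  n_exon_sources: int,
                  n_tf_sources: int,
                  targets_per_tf: int = 3,
                  cis_beta: float = 1.5,
                  trans_beta: float = 1.5,
                  proximal_radius: int = 2,
                  seed: int = 0,
                  prefer_cross_block: bool = True,
                  degree_bias_power: float = 2.0) -> EffectPlan:
    """Choose planted sources, their causal SNPs, and their trans targets.

    Exon sources take one target within ``proximal_radius`` hops, sampled
    with probability proportional to degree**``degree_bias_power``
    (hub-biased; the exponent sets how strongly targets concentrate on
    hubs) and, when
    ``prefer_cross_block`` and block labels exist, from a different planted
    community when possible.  TF sources take ``targets_per_tf`` distinct
    targets from their own planted community.  Every planted target is in a
    trans relation to its source's SNP (different chromosome or >= 1 Mb).
    The planted SNP is the source's highest-MAF eligible SNP — the
    detectability-maximizing choice a power-conscious simulation makes.

    Sources and targets are globally disjoint gene sets (no gene plays two
    roles), exon sources are restricted to non-TF genes, and TF sources are
    planted on intronic SNPs: without this separation, chained effects
    (a target that is itself a source) and cross-scan leakage create strong
    un-planted associations that have no defined ground truth.
    """
    if n_exon_sources < 0 or n_tf_sources < 0 or targets_per_tf < 1:
        raise InvalidParameterError("bad source/target counts")
    if proximal_radius < 1:
        raise InvalidParameterError("proximal_radius must be >= 1")
    ann = annotation_index(annotation)
    rng = np.random.default_rng(seed)
    g = network.graph
    blocks = network.planted_blocks

    snp_pos = {sid: (row["chromosome"], int(row["position"]))
               for sid, row in genotypes.snp_meta.iterrows()}

    def _trans_ok(snp_id: str, target: str) -> bool:
        chrom, pos = snp_pos[snp_id]
        return (target in ann
                and trans_relation(chrom, pos, ann[target]) is not None)

    used: set[str] = set()   # genes already playing a role (source or target)
    entries: list[PlannedEffect] = []

    # --- exon sources -----------------------------------------------------
    exon_candidates = [a.gene_id for a in annotation
                       if not a.is_tf and network.has_node(a.gene_id)]
    rng.shuffle(exon_candidates)
    for gene_id in exon_candidates:
        if len([e for e in entries if e.kind == "exon"]) == n_exon_sources:
            break
        if gene_id in used:
            continue
        snp = _best_snp(genotypes, gene_id, exonic_only=True)
        if snp is None:
            continue
        reach = nx.single_source_shortest_path_length(g, gene_id,
                                                      cutoff=proximal_radius)
        cand = [v for v in reach
                if v != gene_id and v not in used and _trans_ok(snp, v)]
        if not cand:
            continue
        if prefer_cross_block and blocks is not None:
            cross = [v for v in cand if blocks.get(v) != blocks.get(gene_id)]
            if cross:
                cand = cross
        cand.sort()
        weights = np.array([max(g.degree[v], 1) for v in cand],
                           dtype=float) ** degree_bias_power
        target = cand[int(rng.choice(len(cand), p=weights / weights.sum()))]
        entries.append(PlannedEffect(snp_id=snp, source_gene=gene_id,
                                     cis_beta=cis_beta,
                                     targets=((target, trans_beta),),
                                     kind="exon"))
        used.add(gene_id)
        used.add(target)
    n_exon = sum(e.kind == "exon" for e in entries)
    if n_exon < n_exon_sources:
        raise FeasibilityError(
            f"only {n_exon} feasible exon sources, requested {n_exon_sources}")

    # --- TF sources -------------------------------------------------------
    tf_candidates = [a.gene_id for a in annotation
                     if a.is_tf and network.has_node(a.gene_id)]
    rng.shuffle(tf_candidates)
    for gene_id in tf_candidates:
        if len([e for e in entries if e.kind == "tf"]) == n_tf_sources:
            break
        if gene_id in used:
            continue
        snp = _best_snp(genotypes, gene_id, exonic_only=False)
        if snp is None:
            continue
        if blocks is not None:
            pool = [v for v, b in blocks.items() if b == blocks.get(gene_id)]
        else:
            pool = list(g.nodes)
        cand = sorted(v for v in pool
                      if v != gene_id and v not in used and _trans_ok(snp, v))
        if len(cand) < targets_per_tf:
            continue
        chosen = [cand[i] for i in rng.choice(len(cand), size=targets_per_tf,
                                              replace=False)]
        entries.append(PlannedEffect(snp_id=snp, source_gene=gene_id,
                                     cis_beta=cis_beta,
                                     targets=tuple((t, trans_beta)
                                                   for t in sorted(chosen)),
                                     kind="tf"))
        used.add(gene_id)
        used.update(chosen)
    n_tf = sum(e.kind == "tf" for e in entries)
    if n_tf < n_tf_sources:
        raise FeasibilityError(
            f"only {n_tf} feasible TF sources, requested {n_tf_sources}")
    return EffectPlan(entries=tuple(entries), seed=int(seed))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(genotypes: GenotypeMatrix,
                        effect_plan: EffectPlan,
                        annotation: Sequence[GeneAnnotation],
                        noise_sd: float = 1.0,
                        seed: int = 0) -> ExpressionMatrix:
    """Normal-scale expression with the planted causal chains applied.

    Every gene starts as N(0, noise_sd) noise.  Planted source genes gain
    ``cis_beta * dosage`` (missing calls mean-imputed for generation only);
    planted targets then gain ``trans_beta * source expression``, so the
    trans signal flows through the realized source level, noise included.
    """
    if noise_sd <= 0:
        raise InvalidParameterError("noise_sd must be positive")
    genes = [a.gene_id for a in annotation]
    gene_pos = {gid: i for i, gid in enumerate(genes)}
    snp_ids = set(genotypes.snp_meta.index)
    for entry in effect_plan.entries:
        if entry.snp_id not in snp_ids:
            raise ConsistencyError(f"plan SNP {entry.snp_id} not in genotype matrix")
        if entry.source_gene not in gene_pos:
            raise ConsistencyError(f"plan source {entry.source_gene} not annotated")
        for (t, _) in entry.targets:
            if t not in gene_pos:
                raise ConsistencyError(f"plan target {t} not annotated")
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, noise_sd, size=(genotypes.n_samples, len(genes)))
    # cis effects first, then trans effects through the realized source level
    for entry in effect_plan.entries:
        d = genotypes.dosage_vector(entry.snp_id).astype(float)
        obs = d != MISSING
        if not obs.any():
            raise ConsistencyError(f"plan SNP {entry.snp_id} has no observed calls")
        d[~obs] = d[obs].mean()
        values[:, gene_pos[entry.source_gene]] += entry.cis_beta * d
    for entry in effect_plan.entries:
        src = values[:, gene_pos[entry.source_gene]].copy()
        for (t, beta) in entry.targets:
            values[:, gene_pos[t]] += beta * src
    return ExpressionMatrix(samples=list(genotypes.samples), genes=genes,
                            values=values)


# ---------------------------------------------------------------------------
# gene sets and binding pairs
# ---------------------------------------------------------------------------

def generate_gene_sets(annotation: Sequence[GeneAnnotation],
                       partition: ClusterPartition,
                       n_random_sets: int = 4,
                       seed: int = 0,
                       random_set_size_range: tuple[int, int] = (10, 30),
                       ) -> GeneSetCollection:
    """Cluster-aligned categories plus random decoy categories.

    One category per cluster (its exact member set) stands in for the
    functional annotation that real community structure would carry; random
    fixed-size categories provide unenriched decoys.  Background is the full
    annotated gene universe.
    """
    if not partition.assignment:
        raise InvalidParameterError("empty partition")
    background = {a.gene_id for a in annotation}
    stray = set(partition.assignment) - background
    if stray:
        raise ConsistencyError(
            f"partition covers unannotated genes: {sorted(stray)[:5]}")
    categories: dict[str, set[str]] = {
        f"cluster_{cid}": set(members)
        for cid, members in partition.clusters().items()
    }
    rng = np.random.default_rng(seed)
    universe = sorted(background)
    lo, hi = random_set_size_range
    for i in range(n_random_sets):
        k = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(universe), size=min(k, len(universe)), replace=False)
        categories[f"random_{i + 1}"] = {universe[j] for j in idx}
    return GeneSetCollection(categories=categories, background=background)


def generate_binding_pairs(effect_plan: EffectPlan,
                           annotation: Sequence[GeneAnnotation],
                           decoy_fraction: float = 0.5,
                           include_fraction: float = 1.0,
                           seed: int = 0) -> list[tuple[str, str]]:
    """A synthetic TF->target binding-pair list (ChIP-style lookup fixture).

    Includes ``include_fraction`` of the planted TF pairs plus random
    (TF, gene) decoys making up ``decoy_fraction`` of the output list.
    """
    if not (0 <= decoy_fraction < 1) or not (0 <= include_fraction <= 1):
        raise InvalidParameterError("fractions must be in [0, 1) / [0, 1]")
    planted = effect_plan.pairs(kind="tf")
    if not planted:
        raise InvalidParameterError("effect plan contains no TF sources")
    rng = np.random.default_rng(seed)
    n_inc = int(round(include_fraction * len(planted)))
    keep_idx = sorted(rng.choice(len(planted), size=n_inc, replace=False).tolist())
    included = [planted[i] for i in keep_idx]
    out = list(included)
    if decoy_fraction > 0:
        n_decoys = int(round(decoy_fraction / (1 - decoy_fraction) * max(n_inc, 1)))
        tfs = sorted({a.gene_id for a in annotation if a.is_tf})
        genes = sorted(a.gene_id for a in annotation)
        planted_set = set(planted)
        seen = set(included)
        while len(out) - len(included) < n_decoys:
            tf = tfs[int(rng.integers(len(tfs)))]
            gene = genes[int(rng.integers(len(genes)))]
            if gene == tf or (tf, gene) in planted_set or (tf, gene) in seen:
                continue
            seen.add((tf, gene))
            out.append((tf, gene))
    return out


# ---------------------------------------------------------------------------
# the standard planted dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Everything one simulated study produces."""

    annotation: list[GeneAnnotation]
    network: PPINetwork
    genotypes: GenotypeMatrix
    plan: EffectPlan
    expression: ExpressionMatrix
    gene_sets: GeneSetCollection
    binding_pairs: list[tuple[str, str]]


def standard_planted_dataset(seed: int = 0,
                             n_samples: int = 50,
                             n_genes: int = 200,
                             n_chromosomes: int = 5,
                             tf_fraction: float = 0.1,
                             snps_per_gene: int = 3,
                             maf_range: tuple[float, float] = (0.1, 0.45),
                             missing_rate: float = 0.02,
                             n_clusters: int = 4,
                             p_in: float = 0.12,
                             p_out: float = 0.006,
                             n_exon_sources: int = 30,
                             n_tf_sources: int = 6,
                             targets_per_tf: int = 3,
                             cis_beta: float = 1.5,
                             trans_beta: float = 1.5,
                             proximal_radius: int = 2,
                             noise_sd: float = 1.0,
                             degree_bias_power: float = 3.0,
                             n_random_sets: int = 4) -> SimulatedDataset:
    """The reference study conditions used across tests and documentation.

    Network densities give the mean degree of a curated human PPI network
    (~7 edges per node) at 200-node scale; effect sizes and sample size
    match the cohort regime under study (n=50, strong planted effects on
    an already-normalized expression scale).
    """
    annotation = generate_annotation(
        n_genes, n_chromosomes=n_chromosomes, tf_fraction=tf_fraction,
        seed=seed)
    network = generate_ppi_network(
        n_genes, n_clusters, p_in, p_out, seed=seed + 1,
        gene_ids=[a.gene_id for a in annotation])
    genotypes = generate_genotypes(
        n_samples, annotation, snps_per_gene=snps_per_gene,
        maf_range=maf_range, missing_rate=missing_rate, seed=seed + 2)
    plan = plant_effects(
        annotation, network, genotypes, n_exon_sources=n_exon_sources,
        n_tf_sources=n_tf_sources, targets_per_tf=targets_per_tf,
        cis_beta=cis_beta, trans_beta=trans_beta,
        proximal_radius=proximal_radius, degree_bias_power=degree_bias_power,
        seed=seed + 3)
    expression = generate_expression(
        genotypes, plan, annotation, noise_sd=noise_sd, seed=seed + 4)
    gene_sets = generate_gene_sets(
        annotation, partition_from_planted_blocks(network),
        n_random_sets=n_random_sets, seed=seed + 5)
    binding = generate_binding_pairs(
        plan, annotation, decoy_fraction=0.5, include_fraction=1.0,
        seed=seed + 6)
    return SimulatedDataset(annotation=annotation, network=network,
                            genotypes=genotypes, plan=plan,
                            expression=expression, gene_sets=gene_sets,
                            binding_pairs=binding)
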