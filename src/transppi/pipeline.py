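"""End-to-end pipeline driver: simulate -> QC -> scan -> topology -> stats.

The driver strings together the library stages on one configuration object,
writes every result table as TSV/JSON under a run directory, and records a
manifest (parameters, seeds, package version) so that a run is exactly
reproducible from its config alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    best_esnp_per_pair, cis_effect_test, filter_genotypes, pair_summary,
    scan_trans, test_association,
)
from .datatypes import MISSING, Unit
from .enrichment import (
    binding_membership_enrichment, binomial_cis_enrichment, cluster_cooccurrence,
    coexpression_comparison, fisher_2x2, path_category_enrichment,
    positional_bias_test, unit_enrichment,
)
from .errors import InsufficientDataError, InvalidParameterError, NoPathError, TransppiError
from .network import all_pairs_distances, louvain_clusters, shortest_path
from .permutation import (
    derive_seed, sample_length_matched_paths, sample_network_pairs,
    sample_permuted_tf_sets, tf_multiplicity_test,
)
from .simulate import standard_planted_dataset
from .trends import (
    cumulative_property_profile, permuted_trend_distribution, trend_significance,
)
from . import io as tio

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run; round-trips losslessly through YAML."""

    seed: int = 0
    out_dir: str = "transppi_run"
    # simulation (study conditions)
    n_samples: int = 50
    n_genes: int = 200
    n_chromosomes: int = 5
    tf_fraction: float = 0.1
    snps_per_gene: int = 3
    maf_range: tuple[float, float] = (0.1, 0.45)
    missing_rate: float = 0.02
    n_clusters: int = 4
    p_in: float = 0.12
    p_out: float = 0.006
    n_exon_sources: int = 30
    n_tf_sources: int = 6
    targets_per_tf: int = 3
    cis_beta: float = 1.5
    trans_beta: float = 1.5
    proximal_radius: int = 2
    noise_sd: float = 1.0
    degree_bias_power: float = 3.0
    n_random_sets: int = 4
    # QC
    maf_min: float = 0.05
    snp_missing_max: float = 0.1
    sample_missing_max: float = 0.1
    # association thresholds
    exon_p_threshold: float = 1e-6
    tf_p_threshold: float = 1e-6
    candidate_p_threshold: float = 1e-3
    # permutations and enrichment
    n_perm_trend: int = 1000
    n_perm_pairs: int = 5000
    n_tf_sets: int = 1000
    n_path_sets: int = 200
    cis_alpha: float = 0.05
    fdr: float = 0.05
    min_overlap: int = 2

    def validate(self) -> None:
        if not (0 < self.maf_min < 0.5):
            raise InvalidParameterError("maf_min must be in (0, 0.5)")
        for name in ("snp_missing_max", "sample_missing_max", "cis_alpha", "fdr"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise InvalidParameterError(f"{name} must be in (0, 1]")
        for name in ("exon_p_threshold", "tf_p_threshold", "candidate_p_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise InvalidParameterError(f"{name} must be in (0, 1]")
        for name in ("n_perm_trend", "n_perm_pairs", "n_tf_sets", "n_path_sets"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["maf_range"] = list(self.maf_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise InvalidParameterError(f"unknown config keys: {sorted(extra)}")
        if "maf_range" in data:
            data["maf_range"] = tuple(data["maf_range"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _pairs_frame(pairs) -> pd.DataFrame:
    return pd.DataFrame([{
        "esnp": r.esnp_id, "source": r.source_gene, "target": r.target_gene,
        "beta": r.assoc.beta, "se": r.assoc.se, "t": r.assoc.t,
        "p": r.assoc.p, "n_used": r.assoc.n_used, "relation": r.relation,
    } for r in pairs])


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis on a freshly simulated planted dataset.

    Writes all stage outputs under ``config.out_dir`` and returns the
    summary dictionary (also written as ``summary.json``).  Any stage
    failure aborts with the stage name; earlier outputs are preserved.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict[str, Any] = {}
    stage = "simulate"
    try:
        # ------------------------------------------------------------------
        data = standard_planted_dataset(
            seed=config.seed, n_samples=config.n_samples, n_genes=config.n_genes,
            n_chromosomes=config.n_chromosomes, tf_fraction=config.tf_fraction,
            snps_per_gene=config.snps_per_gene, maf_range=config.maf_range,
            missing_rate=config.missing_rate, n_clusters=config.n_clusters,
            p_in=config.p_in, p_out=config.p_out,
            n_exon_sources=config.n_exon_sources, n_tf_sources=config.n_tf_sources,
            targets_per_tf=config.targets_per_tf, cis_beta=config.cis_beta,
            trans_beta=config.trans_beta, proximal_radius=config.proximal_radius,
            noise_sd=config.noise_sd, degree_bias_power=config.degree_bias_power,
            n_random_sets=config.n_random_sets)
        tio.write_annotation_tsv(data.annotation, out / "annotation.tsv")
        tio.write_edge_list(data.network, out / "network_edges.tsv")
        tio.write_vcf(data.genotypes, out / "genotypes.vcf")
        tio.write_expression_tsv(data.expression, out / "expression.tsv")
        tio.write_gmt(data.gene_sets, out / "gene_sets.gmt")
        tio.write_pairs_tsv(data.binding_pairs, out / "binding_pairs.tsv")

        stage = "filter"
        geno = filter_genotypes(data.genotypes, maf_min=config.maf_min,
                                snp_missing_max=config.snp_missing_max,
                                sample_missing_max=config.sample_missing_max)
        expr = data.expression.align_samples(geno.samples)
        summary["qc"] = {"n_snps": geno.n_snps, "n_samples": geno.n_samples}

        stage = "associate"
        exon_pairs = scan_trans(geno, expr, data.annotation, "exonic",
                                config.exon_p_threshold)
        exon_candidates = scan_trans(geno, expr, data.annotation, "exonic",
                                     config.candidate_p_threshold)
        tf_pairs = scan_trans(geno, expr, data.annotation, "tf_span",
                              config.tf_p_threshold)
        tf_candidates = scan_trans(geno, expr, data.annotation, "tf_span",
                                   config.candidate_p_threshold)
        _pairs_frame(exon_pairs).to_csv(out / "exon_pairs.tsv", sep="\t", index=False)
        _pairs_frame(exon_candidates).to_csv(out / "exon_candidates.tsv",
                                             sep="\t", index=False)
        _pairs_frame(tf_pairs).to_csv(out / "tf_pairs.tsv", sep="\t", index=False)
        summary["exon_scan"] = pair_summary(exon_pairs) if exon_pairs else {}
        summary["tf_scan"] = pair_summary(tf_pairs) if tf_pairs else {}

        planted_exon = set(data.plan.pairs(kind="exon"))
        found_exon = {(r.source_gene, r.target_gene) for r in exon_pairs}
        summary["recovery"] = {
            "planted_exon_pairs": len(planted_exon),
            "recovered_exon_pairs": len(planted_exon & found_exon),
            "recovery_fraction": (len(planted_exon & found_exon) / len(planted_exon)
                                  if planted_exon else float("nan")),
        }

        stage = "topology"
        distances = all_pairs_distances(data.network)
        summary["topology"] = {
            "n_nodes": data.network.n_nodes, "n_edges": data.network.n_edges,
            "cross_component_value": distances.cross_component_value,
        }

        stage = "scan_trends"
        trend_pairs = best_esnp_per_pair(exon_candidates) if exon_candidates else []
        try:
            profile = cumulative_property_profile(
                trend_pairs, distances, data.network,
                p_max=config.candidate_p_threshold)
            nulls = permuted_trend_distribution(
                trend_pairs, data.network, distances,
                n_perm=config.n_perm_trend,
                seed=derive_seed(config.seed, "trend_null"),
                p_max=config.candidate_p_threshold)
            trends = trend_significance(profile, nulls)
            pd.DataFrame({
                "threshold": profile.thresholds, "n_pairs": profile.n_pairs,
                **{f"mean_{k}": v for k, v in profile.cumulative_means.items()},
            }).to_csv(out / "trend_profile.tsv", sep="\t", index=False)
            summary["trends"] = trends
        except InsufficientDataError as err:
            log.warning("trend stage skipped: %s", err)
            summary["trends"] = {"skipped": str(err)}

        stage = "cluster"
        partition = louvain_clusters(data.network,
                                     seed=derive_seed(config.seed, "louvain"))
        pd.Series(partition.assignment, name="cluster").rename_axis("node") \
            .to_csv(out / "clusters.tsv", sep="\t")
        summary["clusters"] = {
            "n_clusters": len(partition.clusters()),
            "n_clusters_min2": len(partition.clusters_min_size(2)),
            "modularity_q": partition.modularity_q,
        }

        stage = "enrichment"
        enr: dict[str, Any] = {}

        # cis effects of the best eSNP per exon pair
        if exon_pairs:
            best = best_esnp_per_pair(exon_pairs)
            cis_p = {r.esnp_id: cis_effect_test(r, geno, expr) for r in best}
            sources = {r.source_gene for r in best}
            k_nominal = len({r.source_gene for r in best
                             if cis_p[r.esnp_id] < config.cis_alpha})
            enr["cis"] = {
                "k_nominal": k_nominal, "n_sources": len(sources),
                "binomial_p": binomial_cis_enrichment(k_nominal, len(sources),
                                                      alpha=config.cis_alpha),
            }
            # background: every exonic SNP against its own host gene
            bg_k = bg_n = 0
            meta = geno.snp_meta
            for snp_id in meta.index[meta["exonic"]]:
                host = meta.at[snp_id, "source_gene"]
                if host not in expr.genes:
                    continue
                try:
                    p = test_association(geno.dosage_vector(snp_id),
                                         expr.gene_vector(host)).p
                except TransppiError:
                    continue
                bg_n += 1
                bg_k += p < config.cis_alpha
            _, fisher_p = fisher_2x2(k_nominal, len(sources) - k_nominal,
                                     bg_k, bg_n - bg_k, sided="greater")
            enr["cis"].update({"background_k": bg_k, "background_n": bg_n,
                               "fisher_p": fisher_p})

        # co-expression of exon source-target pairs vs background
        if exon_pairs:
            enr["coexpression"] = coexpression_comparison(
                best_esnp_per_pair(exon_pairs), expr)

        # TF multiplicity vs permuted sets (candidate threshold: the domain
        # scaled to this study's testing burden)
        if tf_candidates:
            real_tf = [(r.source_gene, r.target_gene) for r in tf_candidates]
            perm_sets = sample_permuted_tf_sets(
                real_tf, n_sets=config.n_tf_sets,
                seed=derive_seed(config.seed, "tf_sets_master"))
            mult = tf_multiplicity_test(real_tf, perm_sets)
            enr["tf_multiplicity"] = {
                "statistic": mult["statistic"],
                "empirical_p": mult["empirical_p"],
                "wilcoxon_p": mult["wilcoxon_p"],
            }

            # TF units and their functional enrichment
            units = {}
            for (s, t) in {(r.source_gene, r.target_gene)
                           for r in best_esnp_per_pair(tf_candidates)}:
                units.setdefault(s, set()).add(t)
            unit_objs = [Unit(tf_source=s, targets=frozenset(ts - {s}))
                         for s, ts in units.items() if ts - {s}]
            ue = unit_enrichment(unit_objs, data.gene_sets,
                                 min_overlap=config.min_overlap,
                                 fdr_threshold=config.fdr)
            enr["tf_units"] = {"n_considered": ue["n_considered"],
                               "n_enriched": ue["n_enriched"]}

            # binding-database membership
            null_pairs = sample_permuted_tf_sets(
                real_tf, n_sets=1,
                seed=derive_seed(config.seed, "binding_null"))[0]
            try:
                enr["binding"] = binding_membership_enrichment(
                    real_tf, list(null_pairs.pairs), data.binding_pairs)
            except TransppiError as err:
                enr["binding"] = {"skipped": str(err)}

        # cluster co-occurrence, exon and TF pairs separately
        null_net = sample_network_pairs(
            data.network, min(config.n_perm_pairs,
                              data.network.n_nodes * (data.network.n_nodes - 1) // 4),
            seed=derive_seed(config.seed, "cooccurrence_null"))
        for label, plist in (("exon", exon_candidates), ("tf", tf_candidates)):
            if plist:
                on_net = [r for r in best_esnp_per_pair(plist)
                          if data.network.has_node(r.source_gene)
                          and data.network.has_node(r.target_gene)]
                if on_net:
                    enr[f"cooccurrence_{label}"] = cluster_cooccurrence(
                        on_net, partition, null_net)

        # shortest paths of exon candidate pairs and their annotation content
        if exon_candidates:
            paths = []
            for r in best_esnp_per_pair(exon_candidates):
                if (data.network.has_node(r.source_gene)
                        and data.network.has_node(r.target_gene)):
                    try:
                        paths.append(shortest_path(data.network, r.source_gene,
                                                   r.target_gene))
                    except NoPathError:
                        continue
            if paths:
                pool = []
                pool_pairs = sample_network_pairs(
                    data.network, min(2000, data.network.n_nodes ** 2 // 8),
                    seed=derive_seed(config.seed, "path_pool"))
                for (s, t) in pool_pairs.pairs:
                    try:
                        pool.append(shortest_path(data.network, s, t))
                    except NoPathError:
                        continue
                try:
                    perm_paths = sample_length_matched_paths(
                        pool, [p.length for p in paths],
                        n_sets=config.n_path_sets,
                        seed=derive_seed(config.seed, "path_sets"))
                    enr["paths"] = path_category_enrichment(
                        paths, perm_paths, data.gene_sets)
                except TransppiError as err:
                    enr["paths"] = {"skipped": str(err)}

        # positional bias of exonic eSNPs vs all exonic SNPs
        if exon_pairs:
            meta = geno.snp_meta
            esnp_ids = {r.esnp_id for r in exon_pairs}
            esnp_recs = [(meta.at[s, "source_gene"], int(meta.at[s, "position"]))
                         for s in esnp_ids if meta.at[s, "exonic"]]
            bg_recs = [(row["source_gene"], int(row["position"]))
                       for _, row in meta[meta["exonic"]].iterrows()]
            try:
                enr["positional"] = positional_bias_test(
                    esnp_recs, bg_recs, data.annotation)
            except TransppiError as err:
                enr["positional"] = {"skipped": str(err)}

        summary["enrichment"] = enr

        stage = "report"
        manifest = {
            "package": "transppi", "version": __version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "sub_seeds": {name: derive_seed(config.seed, name)
                          for name in ("trend_null", "louvain", "tf_sets_master",
                                       "cooccurrence_null", "path_pool",
                                       "path_sets", "binding_null")},
            "coordinates": "1-based, closed intervals",
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, default=_json_default))
        return summary
    except TransppiError:
        raise
    except Exception as err:
        raise TransppiError(f"pipeline stage '{stage}' failed: {err}") from err


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
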