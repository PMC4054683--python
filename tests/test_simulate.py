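"""Synthetic-data generators: determinism, distributions, planted structure."""

import numpy as np
import pytest
from scipy import stats

import transppi as tp
from transppi.datatypes import MISSING
from transppi.simulate import (
    generate_annotation, generate_binding_pairs, generate_expression,
    generate_gene_sets, generate_genotypes, generate_ppi_network,
    partition_from_planted_blocks, plant_effects,
)


class TestGenerateAnnotation:
    def test_tf_count_floor(self):
        ann = generate_annotation(10, tf_fraction=0.2, seed=1)
        assert sum(g.is_tf for g in ann) == 2

    def test_two_genes_two_chromosomes(self):
        ann = generate_annotation(2, n_chromosomes=2, seed=0)
        assert ann[0].chromosome != ann[1].chromosome

    def test_deterministic(self):
        a = generate_annotation(30, seed=5)
        b = generate_annotation(30, seed=5)
        assert a == b

    def test_structure_invariants(self):
        ann = generate_annotation(60, n_chromosomes=4, seed=2)
        assert len({g.gene_id for g in ann}) == 60
        by_chrom = {}
        for g in ann:
            assert g.start <= g.end
            prev = None
            for (s, e) in g.exons:
                assert g.start <= s <= e <= g.end
                if prev is not None:
                    assert s > prev
                prev = e
            by_chrom.setdefault(g.chromosome, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 > e1   # non-overlapping spans

    def test_invalid_parameters(self):
        with pytest.raises(tp.InvalidParameterError):
            generate_annotation(1)
        with pytest.raises(tp.InvalidParameterError):
            generate_annotation(10, tf_fraction=1.5)


class TestGeneratePpiNetwork:
    def test_disjoint_cliques_at_extremes(self):
        net = generate_ppi_network(12, 3, p_in=1.0, p_out=0.0, seed=0)
        import networkx as nx
        comps = list(nx.connected_components(net.graph))
        assert len(comps) == 3
        assert all(len(c) == 4 for c in comps)
        for c in comps:
            assert net.graph.subgraph(c).number_of_edges() == 6

    def test_expected_edge_count(self):
        """Edge count within 3 binomial sd of its closed-form mean."""
        n, k, p_in, p_out = 100, 4, 0.3, 0.01
        within_pairs = k * (25 * 24 // 2)
        cross_pairs = (100 * 99 // 2) - within_pairs
        mean = within_pairs * p_in + cross_pairs * p_out
        var = (within_pairs * p_in * (1 - p_in)
               + cross_pairs * p_out * (1 - p_out))
        net = generate_ppi_network(n, k, p_in, p_out, seed=7)
        assert abs(net.n_edges - mean) < 3 * np.sqrt(var)

    def test_louvain_recovery_on_planted_graph(self):
        from sklearn.metrics import adjusted_rand_score
        net = generate_ppi_network(100, 4, p_in=0.3, p_out=0.01, seed=7)
        part = tp.louvain_clusters(net, seed=0)
        nodes = net.nodes()
        ari = adjusted_rand_score([net.planted_blocks[v] for v in nodes],
                                  [part.assignment[v] for v in nodes])
        assert ari > 0.9

    def test_invalid_probabilities(self):
        with pytest.raises(tp.InvalidParameterError):
            generate_ppi_network(10, 2, p_in=1.2, p_out=0.0)
        with pytest.raises(tp.InvalidParameterError):
            generate_ppi_network(10, 2, p_in=0.1, p_out=0.2)


@pytest.fixture(scope="module")
def ann():
    return generate_annotation(20, seed=3)


class TestGenerateGenotypes:

    def test_no_missing_when_rate_zero(self, ann):
        G = generate_genotypes(30, ann, missing_rate=0.0, seed=0)
        assert not (G.dosages == MISSING).any()

    def test_missing_rate_planted(self, ann):
        G = generate_genotypes(200, ann, missing_rate=0.1, seed=0)
        frac = (G.dosages == MISSING).mean()
        assert abs(frac - 0.1) < 0.02

    def test_binomial_moments(self, ann):
        """Mean dosage tracks 2*MAF within 3 sd at a pinned MAF."""
        maf = 0.45
        G = generate_genotypes(2000, ann, snps_per_gene=1,
                               maf_range=(maf, maf), missing_rate=0.0, seed=1)
        means = G.dosages.mean(axis=0)
        sd = np.sqrt(2 * maf * (1 - maf) / 2000)
        assert np.all(np.abs(means - 2 * maf) < 4 * sd)

    def test_exon_boundary_is_exonic(self, ann):
        """Closed intervals: a SNP on an exon boundary base is exonic."""
        gene = ann[0]
        s, e = gene.exons[0]
        assert gene.in_exon(s) and gene.in_exon(e)
        assert not gene.in_exon(e + 1) or gene.in_exon(e + 1) == any(
            a <= e + 1 <= b for (a, b) in gene.exons)

    def test_region_flags_consistent(self, ann):
        G = generate_genotypes(10, ann, seed=2)
        lookup = {g.gene_id: g for g in ann}
        for snp_id, row in G.snp_meta.iterrows():
            gene = lookup[row["source_gene"]]
            assert gene.contains(row["position"])
            assert row["exonic"] == gene.in_exon(row["position"])
            assert row["tf_span"] == gene.is_tf

    def test_invalid_maf_range(self, ann):
        with pytest.raises(tp.InvalidParameterError):
            generate_genotypes(10, ann, maf_range=(0.1, 0.5))


class TestPlantEffects:
    def test_exact_target_counts(self, planted):
        for entry in planted.plan.entries:
            if entry.kind == "tf":
                assert len(entry.targets) == 3
                assert len({t for (t, _) in entry.targets}) == 3
            else:
                assert len(entry.targets) == 1

    def test_all_pairs_trans(self, planted):
        lookup = {g.gene_id: g for g in planted.annotation}
        meta = planted.genotypes.snp_meta
        for entry in planted.plan.entries:
            chrom = meta.at[entry.snp_id, "chromosome"]
            pos = int(meta.at[entry.snp_id, "position"])
            assert meta.at[entry.snp_id, "source_gene"] == entry.source_gene
            for (t, _) in entry.targets:
                assert tp.trans_relation(chrom, pos, lookup[t]) is not None

    def test_exon_targets_within_radius(self, planted):
        dm = tp.all_pairs_distances(planted.network)
        for entry in planted.plan.entries:
            if entry.kind == "exon":
                assert dm.d(entry.source_gene, entry.targets[0][0]) <= 2

    def test_radius_one_targets_adjacent(self, planted):
        plan = plant_effects(planted.annotation, planted.network,
                             planted.genotypes, n_exon_sources=5,
                             n_tf_sources=0, proximal_radius=1, seed=9)
        for entry in plan.entries:
            assert planted.network.graph.has_edge(entry.source_gene,
                                                  entry.targets[0][0])

    def test_targets_degree_biased(self, planted):
        deg = dict(planted.network.graph.degree)
        target_deg = [deg[t] for (_, t) in planted.plan.pairs(kind="exon")]
        assert np.mean(target_deg) > np.mean(list(deg.values()))

    def test_tf_targets_same_block(self, planted):
        blocks = planted.network.planted_blocks
        for entry in planted.plan.entries:
            if entry.kind == "tf":
                for (t, _) in entry.targets:
                    assert blocks[t] == blocks[entry.source_gene]

    def test_infeasible_request(self, planted):
        with pytest.raises(tp.FeasibilityError):
            plant_effects(planted.annotation, planted.network,
                          planted.genotypes, n_exon_sources=500,
                          n_tf_sources=0, seed=0)

    def test_roles_disjoint(self, planted):
        sources = set(planted.plan.source_genes())
        targets = {t for e in planted.plan.entries for (t, _) in e.targets}
        assert not sources & targets


class TestGenerateExpression:
    def test_null_coexpression_small(self):
        """With no planted effects, gene-gene correlations are null-scale."""
        ann = generate_annotation(40, seed=1)
        G = generate_genotypes(50, ann, seed=2)
        plan = tp.EffectPlan(entries=(), seed=0)
        E = generate_expression(G, plan, ann, noise_sd=1.0, seed=3)
        ranks = stats.rankdata(E.values, axis=0)
        corr = np.corrcoef(ranks, rowvar=False)
        iu = np.triu_indices(40, k=1)
        # critical |r| at alpha=0.05, n=50 is about 0.28
        assert np.quantile(np.abs(corr[iu]), 0.95) < 0.35

    def test_cis_beta_recovered_within_three_se(self):
        """Regression of source on dosage recovers the planted slope."""
        ann = generate_annotation(2, n_chromosomes=2, seed=0)
        entry = None
        hits = 0
        reps = 200
        for rep in range(reps):
            G = generate_genotypes(50, ann, snps_per_gene=1,
                                   maf_range=(0.3, 0.3), missing_rate=0.0,
                                   seed=rep)
            snp = G.snp_ids[0]
            plan = tp.EffectPlan(entries=(tp.PlannedEffect(
                snp_id=snp, source_gene=ann[0].gene_id, cis_beta=1.5,
                targets=((ann[1].gene_id, 1.0),), kind="exon"),), seed=rep)
            E = generate_expression(G, plan, ann, noise_sd=1.0, seed=rep + 1)
            st = tp.test_association(G.dosage_vector(snp),
                                     E.gene_vector(ann[0].gene_id))
            hits += abs(st.beta - 1.5) <= 3 * st.se
        assert hits / reps >= 0.95

    def test_deterministic(self, planted):
        E2 = generate_expression(planted.genotypes, planted.plan,
                                 planted.annotation, noise_sd=1.0, seed=5)
        E3 = generate_expression(planted.genotypes, planted.plan,
                                 planted.annotation, noise_sd=1.0, seed=5)
        assert np.array_equal(E2.values, E3.values)

    def test_unknown_gene_rejected(self, planted):
        bad = tp.EffectPlan(entries=(tp.PlannedEffect(
            snp_id=planted.genotypes.snp_ids[0], source_gene="GHOST",
            cis_beta=1.0, targets=(("G0002", 1.0),), kind="exon"),), seed=0)
        with pytest.raises(tp.ConsistencyError):
            generate_expression(planted.genotypes, bad, planted.annotation)


class TestGeneSetsAndBindingPairs:
    def test_cluster_aligned_equals_cluster(self, planted):
        part = partition_from_planted_blocks(planted.network)
        coll = generate_gene_sets(planted.annotation, part, n_random_sets=2,
                                  seed=0)
        for cid, members in part.clusters().items():
            assert coll.categories[f"cluster_{cid}"] == set(members)

    def test_random_category_sizes(self, planted):
        part = partition_from_planted_blocks(planted.network)
        coll = generate_gene_sets(planted.annotation, part, n_random_sets=5,
                                  seed=1, random_set_size_range=(15, 15))
        for i in range(1, 6):
            assert len(coll.categories[f"random_{i}"]) == 15

    def test_decoy_fraction_zero_equals_planted(self, planted):
        pairs = generate_binding_pairs(planted.plan, planted.annotation,
                                       decoy_fraction=0.0, seed=0)
        assert pairs == planted.plan.pairs(kind="tf")

    def test_decoy_fraction_half(self, planted):
        pairs = generate_binding_pairs(planted.plan, planted.annotation,
                                       decoy_fraction=0.5, seed=0)
        planted_set = set(planted.plan.pairs(kind="tf"))
        decoys = [p for p in pairs if p not in planted_set]
        assert len(decoys) == len(planted_set)

    def test_empty_partition_rejected(self, planted):
        from transppi.network import ClusterPartition
        with pytest.raises(tp.InvalidParameterError):
            generate_gene_sets(planted.annotation,
                               ClusterPartition(assignment={}, modularity_q=0),
                               seed=0)


def test_standard_dataset_deterministic():
    a = tp.standard_planted_dataset(seed=3, n_genes=60, n_exon_sources=5,
                                    n_tf_sources=2)
    b = tp.standard_planted_dataset(seed=3, n_genes=60, n_exon_sources=5,
                                    n_tf_sources=2)
    assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
    assert np.array_equal(a.expression.values, b.expression.values)
    assert a.plan == b.plan
    assert sorted(a.network.graph.edges) == sorted(b.network.graph.edges)
    assert a.binding_pairs == b.binding_pairs
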