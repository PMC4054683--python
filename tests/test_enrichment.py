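"""Enrichment statistics: exact tests vs enumeration oracles, comparisons."""

from math import comb

import numpy as np
import pytest

import transppi as tp
from transppi.datatypes import TRANS_DIFF_CHROM
from transppi.network import ClusterPartition, PathRecord


# ---------------------------------------------------------------------------
# enumeration oracles (independent of scipy)
# ---------------------------------------------------------------------------

def fisher_greater_oracle(a, b, c, d):
    """Upper-tail Fisher by enumerating the hypergeometric support."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {k: comb(col1, k) * comb(n - col1, row1 - k) / comb(n, row1)
             for k in range(lo, hi + 1)}
    return sum(p for k, p in probs.items() if k >= a)


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided exact p: sum of outcomes no more probable than observed."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {k: comb(col1, k) * comb(n - col1, row1 - k) / comb(n, row1)
             for k in range(lo, hi + 1)}
    cutoff = probs[a] * (1 + 1e-10)
    return sum(p for p in probs.values() if p <= cutoff)


def hypergeom_tail_oracle(k, M, K, N):
    """P(X >= k) for overlap of a size-N query with a size-K set in M."""
    return sum(comb(K, i) * comb(M - K, N - i) / comb(M, N)
               for i in range(k, min(K, N) + 1))


def binomial_tail_oracle(k, n, p):
    """Strict upper tail P(X > k) by term-wise summation."""
    return sum(comb(n, i) * p ** i * (1 - p) ** (n - i)
               for i in range(k + 1, n + 1))


def ranksum_greater_oracle(a, b):
    """Exact one-sided rank-sum by enumerating all group assignments."""
    from itertools import combinations
    pooled = list(a) + list(b)
    n1 = len(a)
    obs = sum(sorted_rank(pooled, x) for x in a)
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        stat = sum(sorted_rank(pooled, pooled[i]) for i in idx)
        total += 1
        count += stat >= obs
    return count / total


def sorted_rank(pooled, x):
    s = sorted(pooled)
    ranks = [i + 1 for i, v in enumerate(s) if v == x]
    return sum(ranks) / len(ranks)


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

class TestFisher:
    def test_symmetric_table_two_sided(self):
        _, p = tp.fisher_2x2(1, 1, 1, 1, sided="two")
        assert p == pytest.approx(1.0)

    def test_hand_enumerated_upper_tail(self):
        """(3,1,1,3) greater: P(X>=3) = (16+1)/70 = 17/70."""
        _, p = tp.fisher_2x2(3, 1, 1, 3, sided="greater")
        assert p == pytest.approx(17 / 70, rel=1e-12)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = [int(x) for x in rng.integers(0, 8, size=4)]
        _, pg = tp.fisher_2x2(a, b, c, d, sided="greater")
        assert pg == pytest.approx(fisher_greater_oracle(a, b, c, d), rel=1e-9)
        _, p2 = tp.fisher_2x2(a, b, c, d, sided="two")
        assert p2 == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(tp.InvalidParameterError):
            tp.fisher_2x2(-1, 1, 1, 1)


class TestBinomialCisEnrichment:
    def test_strict_tail_by_enumeration(self):
        """(k=2, n=10, alpha=0.5) -> 1 - 56/1024 = 968/1024."""
        assert tp.binomial_cis_enrichment(2, 10, 0.5) == \
            pytest.approx(968 / 1024, rel=1e-12)

    def test_full_success_tail_zero(self):
        assert tp.binomial_cis_enrichment(10, 10, 0.05) == 0.0

    @pytest.mark.parametrize("k,n,alpha", [(3, 12, 0.05), (0, 5, 0.2),
                                           (7, 30, 0.1)])
    def test_matches_oracle(self, k, n, alpha):
        assert tp.binomial_cis_enrichment(k, n, alpha) == \
            pytest.approx(binomial_tail_oracle(k, n, alpha), rel=1e-9)

    def test_invalid_k(self):
        with pytest.raises(tp.InvalidParameterError):
            tp.binomial_cis_enrichment(11, 10)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert tp.benjamini_hochberg([0.37])[0] == pytest.approx(0.37)

    def test_hand_example(self):
        q = tp.benjamini_hochberg([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(tp.benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_order_invariant_and_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        q = tp.benjamini_hochberg(p)
        perm = rng.permutation(20)
        q_perm = tp.benjamini_hochberg(p[perm])
        assert np.allclose(q[perm], q_perm)
        assert np.all(q <= 1.0)

    def test_rejects_bad_input(self):
        with pytest.raises(tp.InvalidParameterError):
            tp.benjamini_hochberg([0.5, 1.5])


class TestHypergeometricEnrichment:
    def collection(self):
        bg = {f"g{i}" for i in range(20)}
        cats = {"hit5": {f"g{i}" for i in range(5)},
                "other": {f"g{i}" for i in range(10, 14)}}
        return tp.GeneSetCollection(categories=cats, background=bg)

    def test_hand_enumerated_tail(self):
        """Query 5, category 5, overlap 4 in background 20: p = 76/15504."""
        query = {"g0", "g1", "g2", "g3", "g15"}
        res = tp.hypergeometric_enrichment(query, self.collection(),
                                           min_overlap=1)
        hit = next(r for r in res if r.category == "hit5")
        assert hit.overlap == 4
        assert hit.p == pytest.approx(76 / 15504, rel=1e-9)
        assert hit.p == pytest.approx(hypergeom_tail_oracle(4, 20, 5, 5),
                                      rel=1e-9)

    def test_zero_overlap_p_one(self):
        res = tp.hypergeometric_enrichment({"g19"}, self.collection(),
                                           min_overlap=0)
        for r in res:
            assert r.overlap == 0
            assert r.p == pytest.approx(1.0)

    def test_min_overlap_excludes_before_testing(self):
        query = {"g0", "g10", "g11"}
        res = tp.hypergeometric_enrichment(query, self.collection(),
                                           min_overlap=2)
        assert {r.category for r in res} == {"other"}

    def test_query_outside_background_rejected(self):
        with pytest.raises(tp.InvalidParameterError):
            tp.hypergeometric_enrichment({"nope"}, self.collection())


# ---------------------------------------------------------------------------
# unit enrichment on the planted fixture
# ---------------------------------------------------------------------------

class TestUnitEnrichment:
    def test_planted_unit_enriched_for_its_cluster(self, planted):
        """A full planted unit hits its own community category hard."""
        entry = next(e for e in planted.plan.entries if e.kind == "tf")
        unit = tp.Unit(tf_source=entry.source_gene,
                       targets=frozenset(t for (t, _) in entry.targets))
        res = tp.unit_enrichment([unit], planted.gene_sets)
        assert res["n_considered"] == 1
        assert res["n_enriched"] == 1
        best = res["per_unit"][entry.source_gene][0]
        assert best.category.startswith("cluster_")
        # all 4 unit genes inside their 50-gene community of 200:
        # exact upper tail is C(50,4)/C(200,4)
        assert best.overlap == 4
        assert best.p == pytest.approx(
            hypergeom_tail_oracle(4, 200, 50, 4), rel=1e-9)
        assert best.q < 0.05

    def test_cluster_aligned_category_hypergeometric(self, planted):
        """A whole cluster queried against its own category: p < 1e-6."""
        part = tp.partition_from_planted_blocks(planted.network)
        cid, members = next(iter(part.clusters().items()))
        res = tp.hypergeometric_enrichment(set(members), planted.gene_sets,
                                           min_overlap=2)
        assert res[0].category == f"cluster_{cid}"
        assert res[0].p < 1e-6


# ---------------------------------------------------------------------------
# expression comparisons
# ---------------------------------------------------------------------------

class TestCoexpression:
    def test_planted_pairs_more_coexpressed(self, planted):
        res = tp.coexpression_comparison(planted.plan.pairs(kind="exon"),
                                         planted.expression)
        assert res["wilcoxon_p"] < 0.01
        assert res["median_abs_r_real"] > res["median_abs_r_background"]

    def test_null_pairs_not_significant_on_average(self):
        """Pairs sampled from the background give calibrated p-values."""
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(40)]
        ps = []
        for rep in range(50):
            E = tp.ExpressionMatrix(
                samples=[f"s{i}" for i in range(30)], genes=genes,
                values=rng.normal(size=(30, 40)))
            pair_list = [tuple(rng.choice(genes, 2, replace=False))
                         for _ in range(8)]
            ps.append(tp.coexpression_comparison(pair_list, E)["wilcoxon_p"])
        assert np.mean(np.array(ps) < 0.05) < 0.2


class TestEffectSizeComparison:
    def test_identical_lists_near_half(self):
        p = tp.effect_size_comparison([1.0, 2.0, 3.0, 4.0],
                                      [1.0, 2.0, 3.0, 4.0])
        assert 0.3 < p < 0.7

    def test_toy_exact_rank_sum(self):
        """3 vs 3 tie-free samples match full-enumeration rank-sum."""
        a, b = [5.0, 6.0, 7.0], [1.0, 2.0, 5.5]
        assert tp.effect_size_comparison(a, b) == \
            pytest.approx(ranksum_greater_oracle(a, b), rel=1e-9)

    def test_shifted_distributions_detected(self):
        rng = np.random.default_rng(1)
        trans = rng.exponential(2.0, size=60)
        cis = rng.exponential(1.0, size=60)
        assert tp.effect_size_comparison(trans, cis) < 0.01


# ---------------------------------------------------------------------------
# cluster co-occurrence and binding membership
# ---------------------------------------------------------------------------

class TestClusterCooccurrence:
    def test_single_cluster_saturated(self):
        part = ClusterPartition(assignment={c: 0 for c in "abcd"},
                                modularity_q=0.0)
        null = tp.RandomPairSet(pairs=(("a", "b"), ("c", "d")),
                                scheme="network_uniform", seed=0)
        res = tp.cluster_cooccurrence([("a", "c")], part, null)
        assert res["real_k"] == 1 and res["null_k"] == 2
        assert res["fisher_p"] == pytest.approx(1.0)

    def test_planted_tf_pairs_cooccur_exon_pairs_do_not(self, planted):
        """TF pairs share communities; cross-community exon pairs do not."""
        part = tp.partition_from_planted_blocks(planted.network)
        null = tp.sample_network_pairs(planted.network, 3000, seed=5)
        tf_res = tp.cluster_cooccurrence(planted.plan.pairs(kind="tf"),
                                         part, null)
        exon_res = tp.cluster_cooccurrence(planted.plan.pairs(kind="exon"),
                                           part, null)
        assert tf_res["fisher_p"] < 0.01
        assert exon_res["fisher_p"] > 0.05


class TestBindingMembership:
    def test_planted_pairs_all_found(self, planted):
        db = set(tp.generate_binding_pairs(planted.plan, planted.annotation,
                                           decoy_fraction=0.0, seed=0))
        assert set(planted.plan.pairs(kind="tf")) == db

    def test_empty_db_rejected(self):
        with pytest.raises(tp.FeasibilityError):
            tp.binding_membership_enrichment([("a", "b")], [("a", "c")], [])

    def test_planted_enrichment_significant(self, planted):
        """Half the planted pairs in the db still separate real from null."""
        db = tp.generate_binding_pairs(planted.plan, planted.annotation,
                                       decoy_fraction=0.5,
                                       include_fraction=0.5, seed=2)
        real = planted.plan.pairs(kind="tf")
        null = tp.sample_random_pairs([s for (s, _) in real],
                                      [t for (_, t) in real],
                                      1000, seed=3).pairs
        res = tp.binding_membership_enrichment(real, list(null), db)
        assert res["fisher_p"] < 0.01


# ---------------------------------------------------------------------------
# path-content comparison
# ---------------------------------------------------------------------------

class TestPathCategoryEnrichment:
    def paths(self):
        return [PathRecord(("s1", "x", "t1")), PathRecord(("s2", "x", "t2"))]

    def test_gene_counted_with_repetition(self):
        """Gene x on two paths contributes 2 to its category's gene count."""
        bg = {"s1", "s2", "t1", "t2", "x", "y"}
        coll = tp.GeneSetCollection(categories={"catx": {"x"}}, background=bg)
        perm = [[PathRecord(("s1", "y", "t1")), PathRecord(("s2", "y", "t2"))]]
        res = tp.path_category_enrichment(self.paths(), perm, coll)
        assert res["catx"]["gene_count"] == 2
        assert res["catx"]["path_count"] == 2
        assert res["catx"]["gene_count_emp_p"] == 0.0

    def test_category_covering_all_genes_p_one(self):
        bg = {"s1", "s2", "t1", "t2", "x", "y"}
        coll = tp.GeneSetCollection(categories={"all": set(bg)}, background=bg)
        perm = [[PathRecord(("s1", "y", "t1")), PathRecord(("s2", "y", "t2"))]
                for _ in range(5)]
        res = tp.path_category_enrichment(self.paths(), perm, coll)
        assert res["all"]["gene_count_emp_p"] == 1.0
        assert res["all"]["path_count_emp_p"] == 1.0

    def test_endpoints_excluded_variant(self):
        bg = {"s1", "s2", "t1", "t2", "x"}
        coll = tp.GeneSetCollection(categories={"ends": {"s1", "t1"}},
                                    background=bg)
        perm = [self.paths()]
        res = tp.path_category_enrichment(self.paths(), perm, coll,
                                          include_endpoints=False)
        assert res["ends"]["gene_count"] == 0

    def test_absent_category_skipped_with_warning(self):
        bg = {"s1", "s2", "t1", "t2", "x"}
        coll = tp.GeneSetCollection(categories={"ok": {"x"}}, background=bg)
        coll.categories["ghost"] = set()   # empty: no background members
        with pytest.warns(UserWarning, match="ghost"):
            res = tp.path_category_enrichment(self.paths(), [self.paths()], coll)
        assert "ghost" not in res


# ---------------------------------------------------------------------------
# positional bias
# ---------------------------------------------------------------------------

class TestPositionalBias:
    def three_exon_gene(self, strand="+"):
        return tp.GeneAnnotation(
            gene_id="G", chromosome="chr1", start=100, end=400, strand=strand,
            exons=((100, 150), (200, 250), (300, 400)))

    def test_bin_assignment_exhaustive(self):
        """Every base of a 3-exon gene lands in the strand-aware bin."""
        from transppi.enrichment import _exon_bin
        g = self.three_exon_gene("+")
        assert _exon_bin(g, 100) == "first"
        assert _exon_bin(g, 150) == "first"
        assert _exon_bin(g, 225) == "middle"
        assert _exon_bin(g, 400) == "last"
        assert _exon_bin(g, 175) is None      # intronic
        rev = self.three_exon_gene("-")
        assert _exon_bin(rev, 100) == "last"
        assert _exon_bin(rev, 400) == "first"

    def test_two_exon_gene_has_no_middle(self):
        from transppi.enrichment import _exon_bin
        g = tp.GeneAnnotation(gene_id="G2", chromosome="chr1", start=1,
                              end=100, strand="+",
                              exons=((1, 20), (80, 100)))
        assert _exon_bin(g, 10) == "first"
        assert _exon_bin(g, 90) == "last"

    def test_transcript_fraction_strand_aware(self):
        from transppi.enrichment import _transcript_fraction
        g = self.three_exon_gene("+")
        assert _transcript_fraction(g, 100) == pytest.approx(0.0)
        g_rev = self.three_exon_gene("-")
        assert _transcript_fraction(g_rev, 400) == pytest.approx(0.0)

    def test_middle_planted_esnps_detected(self):
        """eSNPs concentrated in middle exons give a small Fisher p."""
        g = self.three_exon_gene()
        esnps = [("G", 200 + i) for i in range(30)]          # all middle
        background = ([("G", 100 + i) for i in range(40)]     # first
                      + [("G", 300 + i) for i in range(40)]   # last
                      + [("G", 210 + i) for i in range(20)])  # some middle
        res = tp.positional_bias_test(esnps, background, [g])
        assert res["exon_bin_fisher_p"] < 0.05

    def test_random_subsample_not_biased(self):
        rng = np.random.default_rng(0)
        g = self.three_exon_gene()
        pool = ([("G", int(p)) for p in rng.integers(100, 151, 60)]
                + [("G", int(p)) for p in rng.integers(200, 251, 60)]
                + [("G", int(p)) for p in rng.integers(300, 401, 60)])
        idx = rng.choice(len(pool), 30, replace=False)
        esnps = [pool[i] for i in idx]
        res = tp.positional_bias_test(esnps, pool, [g])
        assert res["exon_bin_fisher_p"] > 0.01
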