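"""Enrichment score, permutation inference, GPD tail, Fisher baseline."""

import numpy as np
import pytest
from scipy import stats

from netora.config import RunConfig
from netora.enrichment import (
    EnrichmentResult,
    InterestingGeneList,
    NullDistribution,
    _final_pvalue,
    adjust_pvalues,
    empirical_pvalue,
    enrichment_score,
    fisher_ora,
    gpd_tail_pvalue,
    permutation_null,
    run_weighted_ora,
)
from netora.network import GeneNetwork
from netora.weighting import GeneSet, GeneSetCollection, contribution_profile

from conftest import random_network

BGNE_N4 = 5 / 6


@pytest.fixture
def profile_n4(n4, set_ab):
    return contribution_profile(n4, set_ab, BGNE_N4)


class TestEnrichmentScore:
    def test_worked_example(self, profile_n4):
        es = enrichment_score(profile_n4, InterestingGeneList(["a", "d"]))
        assert es == pytest.approx(961 / 36)

    def test_single_gene_list(self, profile_n4):
        assert enrichment_score(profile_n4, ["b"]) == pytest.approx(961 / 18)

    def test_out_of_network_genes_ignored(self, profile_n4):
        assert enrichment_score(profile_n4, ["a", "zz"]) == pytest.approx(961 / 18)

    def test_fully_unmatched_list_errors(self, profile_n4):
        with pytest.raises(ValueError):
            enrichment_score(profile_n4, ["zz"])


class TestPermutationNull:
    def test_full_draw_equals_mean_G(self, profile_n4):
        null = permutation_null(profile_n4, n_used=4, N=100, seed=0)
        assert np.allclose(null.samples, profile_n4.G.mean())

    def test_zero_profile_gives_zero_null(self, n4):
        S = GeneSet("S", frozenset(["a", "b"]))
        prof = contribution_profile(n4, S, BGNE_N4)
        prof.G = np.zeros_like(prof.G)
        null = permutation_null(prof, 2, N=100, seed=1)
        assert np.all(null.samples == 0.0)

    def test_deterministic_given_seed(self, profile_n4):
        a = permutation_null(profile_n4, 2, N=200, seed=5)
        b = permutation_null(profile_n4, 2, N=200, seed=5)
        assert np.array_equal(a.samples, b.samples)

    def test_oversized_draw_rejected(self, profile_n4):
        with pytest.raises(ValueError):
            permutation_null(profile_n4, 5, N=100, seed=0)


class TestEmpiricalPvalue:
    def test_counting(self):
        null = NullDistribution(samples=np.arange(1000.0), N=1000, seed=0)
        assert empirical_pvalue(2000.0, null) == pytest.approx(1 / 1001)
        assert empirical_pvalue(-1.0, null) == 1.0
        # 500 samples at or above the median value 500
        assert empirical_pvalue(500.0, null) == pytest.approx(501 / 1001, abs=0.01)


class TestGpdTail:
    def test_requires_enough_samples(self):
        null = NullDistribution(samples=np.random.default_rng(0).normal(size=100),
                                N=100, seed=0)
        small = NullDistribution(samples=null.samples[:100], N=100, seed=0)
        # N >= 100 by type invariant; the tail-fit floor of 30 is below that,
        # so exercise the error through a direct construction bypass
        small.N = 20
        small.samples = small.samples[:20]
        with pytest.raises(ValueError):
            gpd_tail_pvalue(1.0, small)

    def test_exponential_tail_estimates_are_honest(self):
        # truth 1e-4 on a unit exponential: median estimate within a factor
        # of 2, every estimate within an order of magnitude
        ps = []
        for rep in range(25):
            rng = np.random.default_rng(100 + rep)
            null = NullDistribution(rng.exponential(size=10_000), N=10_000, seed=rep)
            p = gpd_tail_pvalue(-np.log(1e-4), null)
            assert p is not None
            ps.append(p)
        ps = np.array(ps)
        assert 0.5e-4 <= np.median(ps) <= 2e-4
        assert np.all((ps >= 1e-5) & (ps <= 1e-3))

    def test_trigger_rule_keeps_empirical_p(self, profile_n4):
        cfg = RunConfig(permutations=1000)
        rng = np.random.default_rng(3)
        samples = rng.normal(size=1000)
        null = NullDistribution(samples=samples, N=1000, seed=0)
        es = np.sort(samples)[-50]  # 50 exceedances: no tail refinement
        p_emp, p_gpd, p_final = _final_pvalue(es, null, cfg)
        assert p_gpd is None
        assert p_final == p_emp

    def test_refinement_fires_below_ten_exceedances(self):
        cfg = RunConfig(permutations=1000)
        rng = np.random.default_rng(4)
        null = NullDistribution(rng.exponential(size=1000), N=1000, seed=0)
        es = null.samples.max() + 5.0
        p_emp, p_gpd, p_final = _final_pvalue(es, null, cfg)
        assert p_gpd is not None
        assert p_final == p_gpd
        assert 0 < p_final < p_emp


class TestAdjustPvalues:
    def test_worked_examples(self):
        assert adjust_pvalues([0.01, 0.04], "bonferroni") == pytest.approx([0.02, 0.08])
        assert adjust_pvalues([0.01, 0.04], "bh") == pytest.approx([0.02, 0.04])

    def test_single_p_unchanged(self):
        for method in ("bonferroni", "bh"):
            assert adjust_pvalues([0.03], method) == pytest.approx([0.03])

    def test_empty_vector(self):
        assert adjust_pvalues([], "bh").size == 0

    def test_ordering_bonferroni_above_bh_above_raw(self):
        rng = np.random.default_rng(7)
        ps = rng.uniform(1e-4, 1, size=50)
        bonf = adjust_pvalues(ps, "bonferroni")
        bh = adjust_pvalues(ps, "bh")
        assert np.all(bonf >= bh - 1e-12)
        assert np.all(bh >= ps - 1e-12)


class TestRunWeightedOra:
    @pytest.fixture
    def small_inputs(self):
        rng = np.random.default_rng(21)
        net = random_network(rng, 40, p=0.15)
        sets = [
            GeneSet(f"s{i}", frozenset(
                net.genes[j] for j in rng.choice(40, size=8, replace=False)))
            for i in range(5)
        ]
        genes = InterestingGeneList(
            [net.genes[j] for j in rng.choice(40, size=10, replace=False)]
        )
        return net, GeneSetCollection(sets), genes

    def test_single_set_bonferroni_equals_final(self, small_inputs):
        net, col, genes = small_inputs
        res = run_weighted_ora(net, GeneSetCollection(col.sets[:1]), genes,
                               RunConfig(permutations=200, seed=1))
        assert res[0].p_bonferroni == pytest.approx(res[0].p_final)

    def test_identical_seed_identical_results(self, small_inputs):
        net, col, genes = small_inputs
        cfg = RunConfig(permutations=200, seed=9)
        r1 = run_weighted_ora(net, col, genes, cfg)
        r2 = run_weighted_ora(net, col, genes, cfg)
        assert r1 == r2

    def test_invariant_to_collection_order(self, small_inputs):
        net, col, genes = small_inputs
        cfg = RunConfig(permutations=200, seed=9)
        r1 = run_weighted_ora(net, col, genes, cfg)
        r2 = run_weighted_ora(net, GeneSetCollection(col.sets[::-1]), genes, cfg)
        assert r1 == r2

    def test_ranks_are_a_permutation(self, small_inputs):
        net, col, genes = small_inputs
        res = run_weighted_ora(net, col, genes, RunConfig(permutations=200, seed=2))
        assert sorted(r.rank for r in res) == list(range(1, len(res) + 1))
        assert all(0 < r.p_final <= 1 for r in res)
        assert all(r.p_bonferroni >= r.p_final for r in res)

    def test_unmatched_list_reported(self, small_inputs):
        net, col, _ = small_inputs
        with pytest.raises(ValueError, match="zz1"):
            run_weighted_ora(net, col, InterestingGeneList(["zz1", "zz2"]))

    def test_empty_filtered_collection_errors(self, small_inputs):
        net, col, genes = small_inputs
        cfg = RunConfig(set_size_min=100, permutations=200)
        with pytest.raises(ValueError, match="filter"):
            run_weighted_ora(net, col, genes, cfg)


class TestFisherBaseline:
    def test_overlap_two_of_two(self):
        col = GeneSetCollection([GeneSet("S", frozenset(["a", "b"]))])
        res = fisher_ora({"a", "b", "c", "d"}, col, InterestingGeneList(["a", "b"]))
        assert res[0].p_final == pytest.approx(1 / 6)

    def test_disjoint_list_gives_p_one(self):
        col = GeneSetCollection([GeneSet("S", frozenset(["a", "b"]))])
        res = fisher_ora({"a", "b", "c", "d"}, col, InterestingGeneList(["c", "d"]))
        assert res[0].p_final == pytest.approx(1.0)

    def test_set_equals_background(self):
        col = GeneSetCollection([GeneSet("S", frozenset("abcd"))])
        res = fisher_ora(set("abcd"), col, InterestingGeneList(["a", "b"]))
        assert res[0].p_final == pytest.approx(1.0)

    def test_matches_hypergeometric_tail(self):
        # independent oracle: hypergeometric survival function
        rng = np.random.default_rng(31)
        background = {f"g{i}" for i in range(40)}
        for _ in range(20):
            k, n = int(rng.integers(2, 15)), int(rng.integers(2, 15))
            members = rng.choice(sorted(background), size=k, replace=False)
            listed = rng.choice(sorted(background), size=n, replace=False)
            col = GeneSetCollection([GeneSet("S", frozenset(members))])
            res = fisher_ora(background, col, InterestingGeneList(list(listed)))
            overlap = len(set(members) & set(listed))
            expected = stats.hypergeom.sf(overlap - 1, 40, k, n)
            assert res[0].p_final == pytest.approx(expected, rel=1e-9)

    def test_empty_background_rejected(self):
        col = GeneSetCollection([GeneSet("S", frozenset(["a"]))])
        with pytest.raises(ValueError):
            fisher_ora(set(), col, InterestingGeneList(["a"]))
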