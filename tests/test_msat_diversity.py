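from itertools import combinations

import numpy as np
import pytest

from conftest import random_matrix
from edgepop.datatypes import MISSING, GenotypeMatrix, LocusMeta, PopulationMap
from edgepop.msat_diversity import (
    allele_frequencies,
    allelic_richness,
    bonferroni,
    expected_heterozygosity,
    f_is,
    gene_diversity,
    genotypic_ld_test,
    hwe_exact_test,
    null_allele_frequency,
    observed_heterozygosity,
    pic,
    private_alleles,
)


def matrix_from_genotypes(genos, name="L1"):
    """Build a one-locus matrix from a list of (a, b) genotypes."""
    calls = np.array([[list(g)] for g in genos])
    meta = LocusMeta(name, 2, (int(calls.min()) - 1, int(calls.max()) + 1))
    return GenotypeMatrix([f"i{k}" for k in range(len(genos))], [meta], calls)


class TestAlleleFrequencies:
    def test_two_individuals_aa_ab(self):
        g = matrix_from_genotypes([(10, 10), (10, 11)])
        t = allele_frequencies(g)
        assert t.n_genes[0] == 4
        assert t.frequencies(0) == {10: 0.75, 11: 0.25}

    def test_all_missing_locus_flagged_empty(self):
        calls = np.full((2, 1, 2), MISSING)
        g = GenotypeMatrix(["a", "b"], [LocusMeta("L", 2, (1, 5))], calls)
        t = allele_frequencies(g)
        assert t.n_genes[0] == 0 and t.frequencies(0) == {}

    def test_matches_bruteforce_tally(self, rng):
        g, pm = random_matrix(rng)
        t = allele_frequencies(g)
        for j in range(g.n_loci):
            tally = {}
            for i in range(g.n_individuals):
                for a in g.calls[i, j]:
                    if a != MISSING:
                        tally[int(a)] = tally.get(int(a), 0) + 1
            assert t.counts[j] == tally
        strat = allele_frequencies(g, stratify=pm)
        assert sum(tab.n_genes.sum() for tab in strat.values()) == t.n_genes.sum()


class TestGeneDiversityPic:
    def test_unbiased_gd_closed_form(self):
        # 10 genes at 0.5/0.5: GD = (10/9)(1 - 0.5) = 0.5556
        g = matrix_from_genotypes([(10, 11)] * 5)
        assert gene_diversity(allele_frequencies(g))[0] == pytest.approx(10 / 9 * 0.5)

    def test_monomorphic_zero(self):
        g = matrix_from_genotypes([(10, 10), (10, 10)])
        assert gene_diversity(allele_frequencies(g))[0] == 0.0

    def test_gd_equals_pairwise_difference_probability(self, rng):
        """Unbiased GD = probability two genes drawn without replacement differ."""
        g, _ = random_matrix(rng, missing_rate=0.0)
        t = allele_frequencies(g)
        gd = gene_diversity(t)
        for j in range(g.n_loci):
            genes = g.calls[:, j, :].ravel()
            pairs = list(combinations(genes, 2))
            brute = np.mean([a != b for a, b in pairs])
            assert gd[j] == pytest.approx(brute)

    def test_pic_values(self):
        g = matrix_from_genotypes([(10, 11)] * 5)
        assert pic(allele_frequencies(g))[0] == pytest.approx(0.375)
        mono = matrix_from_genotypes([(10, 10)])
        assert pic(allele_frequencies(mono))[0] == 0.0
        # 4 equifrequent alleles: 1 - 1/4 - 2*6*(1/16)^2 = 0.703125
        g4 = matrix_from_genotypes([(10, 11), (12, 13)])
        assert pic(allele_frequencies(g4))[0] == pytest.approx(0.703125)

    def test_pic_below_plugin_he_everywhere(self, rng):
        g, _ = random_matrix(rng)
        t = allele_frequencies(g)
        assert (pic(t) <= expected_heterozygosity(t) + 1e-12).all()


class TestAllelicRichness:
    def test_counts_9_1_g2_by_enumeration(self):
        # all C(10,2) 2-gene subsets: expected distinct alleles
        genes = [0] * 9 + [1]
        brute = np.mean([len(set(p)) for p in combinations(genes, 2)])
        g = matrix_from_genotypes([(10, 10)] * 4 + [(10, 11)])
        ar = allelic_richness(allele_frequencies(g), g=2)
        assert ar[0] == pytest.approx(brute) == pytest.approx(1.2)

    def test_monomorphic_is_one(self):
        g = matrix_from_genotypes([(10, 10)] * 5)
        assert allelic_richness(allele_frequencies(g), g=4)[0] == pytest.approx(1.0)

    def test_full_sample_recovers_allele_count(self, rng):
        g, _ = random_matrix(rng, missing_rate=0.0)
        t = allele_frequencies(g)
        ar = allelic_richness(t, g=int(t.n_genes[0]))
        assert np.allclose(ar, t.n_alleles())

    def test_monotone_in_g(self, rng):
        g, _ = random_matrix(rng, missing_rate=0.0)
        t = allele_frequencies(g)
        prev = None
        for size in range(2, int(t.n_genes.min()) + 1):
            ar = allelic_richness(t, g=size)
            if prev is not None:
                assert (ar >= prev - 1e-12).all()
            prev = ar


class TestFis:
    def test_all_heterozygotes_is_minus_one(self):
        g = matrix_from_genotypes([(10, 11)] * 6)
        res = f_is(g, n_perm=10, seed=1)
        assert res.loc["L1", "fis"] == pytest.approx(-1.0)

    def test_hwe_proportions_near_zero(self):
        rng = np.random.default_rng(7)
        genes = rng.integers(10, 14, size=(500, 1, 2))
        g = GenotypeMatrix(
            [f"i{k}" for k in range(500)], [LocusMeta("L", 2, (9, 15))], genes
        )
        res = f_is(g, n_perm=10, seed=1)
        assert abs(res.loc["overall", "fis"]) < 0.08

    def test_permutation_p_flags_structure(self):
        # strong heterozygote deficit: only homozygotes at a 50/50 locus
        g = matrix_from_genotypes([(10, 10)] * 8 + [(11, 11)] * 8)
        res = f_is(g, n_perm=400, seed=3)
        assert res.loc["L1", "fis"] == pytest.approx(1.0)
        assert res.loc["L1", "p_value"] < 0.05


class TestNullAlleles:
    def test_ho_equals_he_gives_zero(self):
        g = matrix_from_genotypes([(10, 11), (10, 10), (11, 11), (10, 11)])
        # Ho = 0.5, plug-in He = 0.5
        est = null_allele_frequency(g)
        assert est.loc["L1", "chakraborty"] == pytest.approx(0.0)
        assert est.loc["L1", "brookfield1"] == pytest.approx(0.0)

    def test_he_05_ho_04(self):
        g = matrix_from_genotypes(
            [(10, 11)] * 4 + [(10, 10)] * 3 + [(11, 11)] * 3
        )
        t = allele_frequencies(g)
        assert expected_heterozygosity(t)[0] == pytest.approx(0.5)
        assert observed_heterozygosity(g)[0] == pytest.approx(0.4)
        est = null_allele_frequency(g)
        assert est.loc["L1", "chakraborty"] == pytest.approx(0.1 / 0.9)
        assert est.loc["L1", "brookfield1"] == pytest.approx(0.1 / 1.5)


class TestHwe:
    def test_levene_enumeration_3aa_0ab_3bb(self):
        """Full enumeration over margins (6 A, 6 B): p = 20/924."""
        g = matrix_from_genotypes([(10, 10)] * 3 + [(11, 11)] * 3)
        res = hwe_exact_test(g, "L1", seed=1)
        assert res.loc["all", "method"] == "enumeration"
        assert res.loc["all", "p_value"] == pytest.approx(20 / 924)

    def test_monte_carlo_agrees_with_enumeration(self):
        g = matrix_from_genotypes([(10, 10)] * 3 + [(11, 11)] * 3)
        res = hwe_exact_test(g, "L1", enum_cap=0, n_mc=40_000, seed=5)
        assert res.loc["all", "method"] == "monte-carlo"
        assert res.loc["all", "p_value"] == pytest.approx(20 / 924, abs=0.004)

    def test_perfect_proportions_large_sample_p_near_one(self):
        genos = [(10, 10)] * 25 + [(10, 11)] * 50 + [(11, 11)] * 25
        g = matrix_from_genotypes(genos)
        res = hwe_exact_test(g, "L1", seed=1)
        assert res.loc["all", "p_value"] > 0.5

    def test_monomorphic_not_testable(self):
        g = matrix_from_genotypes([(10, 10)] * 4)
        res = hwe_exact_test(g, "L1", seed=1)
        assert res.loc["all", "p_value"] == 1.0
        assert res.loc["all", "method"] == "not testable"

    def test_enumeration_probabilities_sum_to_one(self):
        from edgepop.msat_diversity import _enumerate_tables, _log_table_weight
        from scipy.special import gammaln

        counts = np.array([6, 4, 2])
        tables = _enumerate_tables(counts, cap=10_000)
        n = counts.sum() // 2
        log_const = (
            gammaln(n + 1)
            + sum(gammaln(c + 1) for c in counts)
            - gammaln(2 * n + 1)
        )
        total = sum(np.exp(log_const + _log_table_weight(t)) for t in tables)
        assert total == pytest.approx(1.0)


def test_bonferroni_threshold_arithmetic():
    calls = bonferroni([0.004] + [0.5] * 9)
    assert calls[0] and not calls[1:].any()
    assert not bonferroni([0.006] + [0.5] * 9)[0]
    assert bonferroni([0.04]).all() and not bonferroni([0.06]).any()


class TestLd:
    def test_duplicated_locus_maximal_association(self):
        # few distinct genotypes, unbalanced counts: permutations cannot
        # recreate the perfect two-locus association except by rare ties
        genos = [(10, 10)] * 9 + [(10, 11)] * 7 + [(11, 11)] * 4
        g = matrix_from_genotypes(genos)
        calls = np.concatenate([g.calls, g.calls], axis=1)
        g2 = GenotypeMatrix(
            g.individuals,
            [g.loci[0], LocusMeta("Ldup", 2, g.loci[0].allele_range)],
            calls,
        )
        res = genotypic_ld_test(g2, n_perm=200, seed=1)
        assert len(res) == 1
        assert res["p_value"].iloc[0] == pytest.approx(1 / 201)

    def test_single_polymorphic_locus_empty(self):
        g = matrix_from_genotypes([(10, 11), (10, 10)])
        assert genotypic_ld_test(g, n_perm=10).empty

    def test_independent_loci_p_not_extreme(self, rng):
        g, pm = random_matrix(rng, n_loci=3, n_ind=30, missing_rate=0.0)
        res = genotypic_ld_test(g, pm, n_perm=300, seed=2)
        assert (res["p_value"] > 0.01).all()


class TestPrivateAlleles:
    def test_counts_and_bruteforce(self, rng):
        g, pm = random_matrix(rng, n_ind=16, n_pops=3)
        counts = private_alleles(g, pm)
        tables = allele_frequencies(g, stratify=pm)
        pops = list(tables)
        expected = dict.fromkeys(pops, 0)
        for j in range(g.n_loci):
            for p in pops:
                mine = set(tables[p].counts[j])
                rest = set()
                for q in pops:
                    if q != p:
                        rest |= set(tables[q].counts[j])
                expected[p] += len(mine - rest)
        assert counts.to_dict() == expected

    def test_shared_alleles_give_zero(self):
        g = matrix_from_genotypes([(10, 11), (10, 11), (10, 11), (11, 10)])
        pm = PopulationMap({"i0": "a", "i1": "a", "i2": "b", "i3": "b"})
        assert (private_alleles(g, pm) == 0).all()
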