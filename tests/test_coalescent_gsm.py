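import numpy as np
import pytest

from edgepop.coalescent_gsm import (
    MutationModel,
    PriorSpec,
    ScenarioSpec,
    mutate_gsm,
    sample_prior,
    simulate_dataset,
    simulate_genealogy,
    simulate_stats_batch,
    summary_stats,
)
from edgepop.datatypes import GenotypeMatrix, LocusMeta
from edgepop.msat_diversity import allele_frequencies, gene_diversity


class TestPriors:
    def test_degenerate_prior_constant(self, rng):
        ps = PriorSpec({"Ne": (100.0, 100.0)})
        draws = {sample_prior(ps, 1, rng)["Ne"] for _ in range(20)}
        assert draws == {100.0}

    def test_scenario4_ordering_constraints_always_hold(self, rng):
        ps = PriorSpec()
        for _ in range(2000):
            d = sample_prior(ps, 4, rng)
            assert d["t1"] < d["t2"]
            assert d["Nb"] < d["Ne4"] and d["Nb"] < d["Na4"]

    def test_unconstrained_marginal_uniform(self, rng):
        from scipy.stats import kstest

        ps = PriorSpec()
        draws = np.array([sample_prior(ps, 1, rng)["Ne"] for _ in range(4000)])
        lo, hi = ps.bounds["Ne"]
        stat = kstest((draws - lo) / (hi - lo), "uniform")
        assert stat.pvalue > 1e-3


class TestGenealogy:
    def test_pair_tmrca_constant_size(self, rng):
        spec = ScenarioSpec(1)
        times = [
            simulate_genealogy(spec, {"Ne": 500}, 2, rng)[1][-1] for _ in range(4000)
        ]
        # E[TMRCA] = 2N, sd = 2N for a pair
        se = 2 * 500 / np.sqrt(4000)
        assert np.mean(times) == pytest.approx(2 * 500, abs=3 * se)

    def test_always_small_reduces_to_constant(self, rng):
        spec = ScenarioSpec(2)
        params = {"Ne2": 50, "Na2": 50000, "t": 1e9}  # boundary never reached
        times = [simulate_genealogy(spec, params, 2, rng)[1][-1] for _ in range(3000)]
        se = 100 / np.sqrt(3000)
        assert np.mean(times) == pytest.approx(100, abs=3 * se)

    def test_two_epoch_tmrca_matches_msprime(self, rng):
        """Independent-oracle check of the epoch-boundary rescaling."""
        msprime = pytest.importorskip("msprime")
        from scipy.stats import ks_2samp

        N0, N1, t_sw, n = 200.0, 5000.0, 300.0, 6
        spec = ScenarioSpec(2)
        ours = np.array(
            [
                simulate_genealogy(spec, {"Ne2": N0, "Na2": N1, "t": t_sw}, n, rng)[1][-1]
                for _ in range(1500)
            ]
        )
        dem = msprime.Demography()
        # ploidy-1 samples with size 2N reproduce the 1/(2N) pair rate
        dem.add_population(name="A", initial_size=2 * N0)
        dem.add_population_parameters_change(time=t_sw, initial_size=2 * N1)
        theirs = np.array(
            [
                msprime.sim_ancestry(
                    samples={"A": n}, demography=dem, ploidy=1, random_seed=s + 1
                ).max_root_time
                for s in range(1500)
            ]
        )
        assert ks_2samp(ours, theirs).pvalue > 1e-3

    def test_invalid_scenario_and_sizes_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(5)
        with pytest.raises(ValueError):
            ScenarioSpec(1).epochs({"Ne": 1})


class TestMutation:
    def test_rate_zero_monomorphic(self, rng):
        meta = LocusMeta("L", 2, (5, 35))
        tree = simulate_genealogy(ScenarioSpec(1), {"Ne": 1000}, 10, rng)
        tips = mutate_gsm(tree, meta, 0.0, 0.5, rng)
        assert (tips == 20).all()

    def test_step_second_moment_matches_geometric_law(self, rng):
        """E[step^2] for step = 1 + G, G ~ Geom0(P)."""
        from edgepop.coalescent_gsm import _branch_displacement, _seed_kernel

        p = 0.4
        _seed_kernel(123)
        draws = np.array([_branch_displacement(1, p) for _ in range(60_000)])
        eg = (1 - p) / p
        eg2 = (1 - p) * (2 - p) / p**2
        expected = 1 + 2 * eg + eg2
        assert np.mean(draws**2) == pytest.approx(expected, rel=0.05)
        assert abs(np.mean(draws)) < 0.05  # signs equiprobable

    def test_tips_respect_allele_range(self, rng):
        meta = LocusMeta("L", 2, (10, 14))
        for _ in range(30):
            tree = simulate_genealogy(ScenarioSpec(1), {"Ne": 2000}, 12, rng)
            tips = mutate_gsm(tree, meta, 5e-3, 0.2, rng)
            assert tips.min() >= 10 and tips.max() <= 14

    def test_smm_gene_diversity_matches_ohta_kimura_theta2(self, rng):
        # equilibrium GD = 1 - 1/sqrt(1 + 8 N mu); theta = 4 N mu = 2
        N, n_rep = 4000, 400
        mu = 2 / (4 * N)
        meta = LocusMeta("L", 2, (0, 2 * 10**6))  # effectively unbounded
        vals = []
        for _ in range(n_rep):
            tree = simulate_genealogy(ScenarioSpec(1), {"Ne": N}, 50, rng)
            tips = mutate_gsm(tree, meta, mu, 1.0, rng)
            g = GenotypeMatrix(
                [f"i{k}" for k in range(25)], [meta],
                tips.reshape(25, 1, 2),
            )
            vals.append(gene_diversity(allele_frequencies(g))[0])
        expect = 1 - 1 / np.sqrt(5)
        se = np.std(vals) / np.sqrt(n_rep)
        assert np.mean(vals) == pytest.approx(expect, abs=3 * se)


class TestDatasets:
    def test_single_individual_rate_zero_midpoint_homozygote(self, rng):
        meta = LocusMeta("L", 2, (10, 20))
        g = simulate_dataset(
            ScenarioSpec(1), {"Ne": 100}, [meta], 1, rng,
            rates=np.array([0.0]), p_gsm=np.array([0.5]),
        )
        assert tuple(g.calls[0, 0]) == (15, 15)

    def test_same_seed_identical(self):
        meta = [LocusMeta(f"L{j}", 2, (5, 35)) for j in range(3)]
        a = simulate_dataset(
            ScenarioSpec(1), {"Ne": 500}, meta, 8, np.random.default_rng(42)
        )
        b = simulate_dataset(
            ScenarioSpec(1), {"Ne": 500}, meta, 8, np.random.default_rng(42)
        )
        assert np.array_equal(a.calls, b.calls)

    def test_bottleneck_lowers_allele_count_and_m(self, rng):
        panel = [LocusMeta(f"L{j}", 2, (5, 35)) for j in range(5)]
        n_rep = 60
        mut = MutationModel(mu_mean_bounds=(5e-4, 5e-4))
        # ongoing bottleneck: allele count collapses faster than size range
        draws2 = [{"Ne2": 500, "Na2": 100_000, "t": 500}] * n_rep
        draws1 = [{"Ne": 100_000}] * n_rep
        s2 = simulate_stats_batch(ScenarioSpec(2), draws2, panel, 20, rng, mut)
        s1 = simulate_stats_batch(ScenarioSpec(1), draws1, panel, 20, rng, mut)
        assert s2[:, 0].mean() < s1[:, 0].mean()  # fewer alleles
        assert s2[:, 3].mean() < s1[:, 3].mean()  # Garza-Williamson M depressed


class TestSummaryStats:
    def test_monomorphic_vector(self):
        meta = LocusMeta("L", 2, (5, 15))
        calls = np.full((4, 1, 2), 10)
        g = GenotypeMatrix([f"i{k}" for k in range(4)], [meta], calls)
        assert np.allclose(summary_stats(g), [1.0, 0.0, 0.0, 1.0])

    def test_hand_computed_case(self):
        # gene copies {10, 10, 12, 14}: A=3, var=2.75 (denominator n), M=3/5
        meta = LocusMeta("L", 2, (5, 20))
        calls = np.array([[[10, 10]], [[12, 14]]])
        g = GenotypeMatrix(["a", "b"], [meta], calls)
        stats = summary_stats(g)
        assert stats[0] == 3
        assert stats[2] == pytest.approx(2.75)
        assert stats[3] == pytest.approx(0.6)

    def test_agrees_with_diversity_module(self, rng):
        from conftest import random_matrix

        g, _ = random_matrix(rng, missing_rate=0.0)
        stats = summary_stats(g)
        freqs = allele_frequencies(g)
        assert stats[0] == pytest.approx(freqs.n_alleles().mean())
        assert stats[1] == pytest.approx(np.nanmean(gene_diversity(freqs)))
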