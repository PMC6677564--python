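import numpy as np
import pandas as pd
import pytest

from edgepop.abc_inference import (
    STAT_NAMES,
    ReferenceTable,
    build_reference_table,
    estimate_parameters,
    model_choice_direct,
    model_choice_logistic,
    posterior_model_check,
    predictive_error,
)
from edgepop.coalescent_gsm import ALL_PARAMS, MutationModel, PriorSpec
from edgepop.datatypes import LocusMeta

PANEL = [LocusMeta(f"L{j}", 2, (5, 35)) for j in range(3)]


def toy_table(rng, n_per=300, centers=None):
    """Hand-built reference table with Gaussian stat clusters per scenario."""
    centers = centers or {1: 0.0, 2: 4.0, 3: 8.0, 4: 12.0}
    sids, stats, params = [], [], []
    for sid, c in centers.items():
        s = rng.normal(c, 1.0, size=(n_per, 4))
        stats.append(s)
        sids.append(np.full(n_per, sid))
        params.append(np.full((n_per, len(ALL_PARAMS)), np.nan))
    stats = np.vstack(stats)
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0)
    return ReferenceTable(
        scenario_ids=np.concatenate(sids),
        params=pd.DataFrame(np.vstack(params), columns=ALL_PARAMS),
        stats=stats,
        stat_names=list(STAT_NAMES),
        medians=med,
        mads=mad,
        seed=0,
    )


class TestReferenceTable:
    def test_smoke_row_counts_and_determinism(self):
        priors = PriorSpec()
        rt1 = build_reference_table([1, 2, 3, 4], priors, PANEL, 6, 10, seed=3)
        rt2 = build_reference_table([1, 2, 3, 4], priors, PANEL, 6, 10, seed=3)
        assert rt1.n_rows == 40
        assert sorted(rt1.scenarios()) == [1, 2, 3, 4]
        assert np.array_equal(rt1.stats, rt2.stats)
        assert rt1.params.equals(rt2.params)

    def test_bottleneck_scenario_lowers_mean_m(self):
        # ongoing bottleneck (t ~ Ne2 generations): alleles are lost faster
        # than the allele-size range, the Garza-Williamson signature
        priors = PriorSpec(
            {
                "Ne": (100_000.0, 100_000.0),
                "Ne2": (500.0, 500.0),
                "Na2": (100_000.0, 100_000.0),
                "t": (500.0, 500.0),
            }
        )
        mut = MutationModel(mu_mean_bounds=(5e-4, 5e-4))
        rt = build_reference_table([1, 2], priors, PANEL, 15, 60, seed=5, mutation=mut)
        m = rt.stats[:, 3]
        assert m[rt.scenario_ids == 2].mean() < m[rt.scenario_ids == 1].mean()

    def test_save_load_roundtrip(self, tmp_path, rng):
        rt = toy_table(rng, n_per=20)
        path = tmp_path / "rt.npz"
        rt.save(path)
        back = ReferenceTable.load(path)
        assert np.array_equal(back.stats, rt.stats)
        assert np.array_equal(back.scenario_ids, rt.scenario_ids)


class TestModelChoice:
    def test_direct_separable_and_sums_to_one(self, rng):
        rt = toy_table(rng)
        res = model_choice_direct(np.full(4, 4.0), rt, k_direct=50)
        assert res.direct.sum() == pytest.approx(1.0)
        assert res.best("direct") == 2
        assert res.direct[2] > 0.9

    def test_direct_symmetric_when_identical(self, rng):
        rt = toy_table(rng, centers={1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0})
        probs = []
        for _ in range(30):
            obs = rng.normal(0, 1, size=4)
            probs.append(model_choice_direct(obs, rt, k_direct=200).direct.values)
        assert np.allclose(np.mean(probs, axis=0), 0.25, atol=0.05)

    def test_direct_k_equal_table_recovers_prior_proportions(self, rng):
        rt = toy_table(rng, n_per=100)
        res = model_choice_direct(np.zeros(4), rt, k_direct=rt.n_rows)
        assert np.allclose(res.direct.values, 0.25)

    def test_logistic_separable(self, rng):
        rt = toy_table(rng)
        res = model_choice_logistic(np.full(4, 4.0), rt, k_logistic=600)
        assert res.logistic.sum() == pytest.approx(1.0, abs=1e-6)
        assert res.best("logistic") == 2
        assert res.logistic[2] > 0.9

    def test_logistic_shuffled_labels_near_uniform(self, rng):
        rt = toy_table(rng)
        rt.scenario_ids = rng.permutation(rt.scenario_ids)
        res = model_choice_logistic(np.full(4, 6.0), rt, k_logistic=rt.n_rows)
        assert np.allclose(res.logistic.values, 0.25, atol=0.1)

    def test_normalization_cancels_affine_rescaling(self, rng):
        rt = toy_table(rng)
        obs = np.full(4, 4.0)
        base_d = model_choice_direct(obs, rt, k_direct=50).direct
        base_l = model_choice_logistic(obs, rt, k_logistic=400).logistic
        scaled = ReferenceTable(
            scenario_ids=rt.scenario_ids.copy(),
            params=rt.params.copy(),
            stats=rt.stats * 100.0 + 7.0,
            stat_names=rt.stat_names,
            medians=rt.medians * 100.0 + 7.0,
            mads=rt.mads * 100.0,
            seed=0,
        )
        obs2 = obs * 100.0 + 7.0
        assert np.allclose(
            model_choice_direct(obs2, scaled, k_direct=50).direct, base_d
        )
        assert np.allclose(
            model_choice_logistic(obs2, scaled, k_logistic=400).logistic,
            base_l,
            atol=1e-6,
        )

    def test_logistic_ci_brackets_estimate(self, rng):
        rt = toy_table(rng)
        res = model_choice_logistic(np.full(4, 2.0), rt, k_logistic=600)
        if res.logistic_ci is not None:
            assert (res.logistic_ci["low"] <= res.logistic + 1e-9).all()
            assert (res.logistic_ci["high"] >= res.logistic - 1e-9).all()


class TestParameterEstimation:
    def _linear_table(self, rng, n=3000, noise=0.02):
        """stat = theta + small noise: the adjustment should sharpen."""
        theta = rng.uniform(10, 500_000, size=n)
        stats = np.column_stack(
            [theta + rng.normal(0, noise * 500_000, n)]
            + [rng.normal(0, 1, n) for _ in range(3)]
        )
        med = np.median(stats, axis=0)
        mad = np.median(np.abs(stats - med), axis=0)
        params = pd.DataFrame(np.nan, index=range(n), columns=ALL_PARAMS)
        params["Ne"] = theta
        return ReferenceTable(
            scenario_ids=np.full(n, 1),
            params=params,
            stats=stats,
            stat_names=list(STAT_NAMES),
            medians=med,
            mads=mad,
            seed=0,
        )

    def test_adjustment_beats_rejection_on_linear_model(self, rng):
        rt = self._linear_table(rng)
        priors = PriorSpec()
        truth = 200_000.0
        obs = np.array([truth, 0.0, 0.0, 0.0])
        post = estimate_parameters(obs, rt, 1, priors, k_est=500)
        adj_rmse = np.sqrt(np.mean((post.samples["Ne"] - truth) ** 2))
        mask = rt.scenario_ids == 1
        d = rt.distances(obs)
        rej = rt.params.loc[mask, "Ne"].to_numpy()[np.argsort(d[mask])[:500]]
        rej_rmse = np.sqrt(np.mean((rej - truth) ** 2))
        assert adj_rmse < rej_rmse
        assert post.q050["Ne"] <= truth <= post.q950["Ne"]
        assert post.mode["Ne"] == pytest.approx(truth, rel=0.1)

    def test_zero_spread_obs_keeps_rejection_posterior(self, rng):
        n = 200
        params = pd.DataFrame(np.nan, index=range(n), columns=ALL_PARAMS)
        params["Ne"] = rng.uniform(100, 1000, n)
        stats = np.tile([1.0, 2.0, 3.0, 4.0], (n, 1))
        rt = ReferenceTable(
            scenario_ids=np.full(n, 1), params=params, stats=stats,
            stat_names=list(STAT_NAMES),
            medians=stats[0], mads=np.ones(4), seed=0,
        )
        post = estimate_parameters(np.array([1.0, 2.0, 3.0, 4.0]), rt, 1, PriorSpec(), k_est=n)
        assert not post.adjusted
        assert np.allclose(
            np.sort(post.samples["Ne"]), np.sort(params["Ne"]), rtol=1e-6
        )

    def test_estimates_within_prior_bounds(self, rng):
        rt = self._linear_table(rng, n=1000)
        priors = PriorSpec()
        post = estimate_parameters(
            np.array([450_000.0, 0, 0, 0]), rt, 1, priors, k_est=300
        )
        lo, hi = priors.bounds["Ne"]
        assert (post.samples["Ne"] >= lo).all() and (post.samples["Ne"] <= hi).all()
        assert post.q050["Ne"] <= post.q950["Ne"]


class TestPredictiveErrorAndChecking:
    def test_separable_scenarios_error_zero(self):
        priors = PriorSpec(
            {
                "Ne": (50.0, 60.0),
                "Ne2": (30_000.0, 40_000.0),
                "Na2": (400_000.0, 450_000.0),
                "t": (5_000.0, 6_000.0),
            }
        )
        mut = MutationModel(mu_mean_bounds=(1e-3, 1e-3))
        rt = build_reference_table([1, 2], priors, PANEL, 12, 150, seed=9, mutation=mut)
        err, per = predictive_error(
            priors, rt, PANEL, 12, n_pods=10, seed=11, mutation=mut, k=25
        )
        assert err == 0.0
        assert set(per.index) == {1, 2}

    def test_pod_count_validation(self, rng):
        rt = toy_table(rng)
        with pytest.raises(ValueError):
            predictive_error(PriorSpec(), rt, PANEL, 6, n_pods=0, seed=1)

    def test_model_check_flags_outlier_and_degenerate(self, rng):
        priors = PriorSpec({"Ne": (500.0, 1000.0)})
        mut = MutationModel(mu_mean_bounds=(1e-3, 1e-3))
        rt = build_reference_table([1], priors, PANEL, 10, 120, seed=2, mutation=mut)
        obs = rt.stats[rt.n_rows // 2]
        post = estimate_parameters(obs, rt, 1, priors, k_est=60)
        check = posterior_model_check(obs, 1, post, PANEL, 10, n_ppc=80, seed=3, mutation=mut)
        assert not check["poor_fit"].all()  # typical obs fits
        far = obs.copy()
        far[0] = 1e6
        check2 = posterior_model_check(far, 1, post, PANEL, 10, n_ppc=80, seed=3, mutation=mut)
        assert check2.loc["mean_A", "tail_prob"] == 1.0
        assert check2.loc["mean_A", "poor_fit"]
        with pytest.warns(UserWarning):
            posterior_model_check(obs, 1, post, PANEL, 10, n_ppc=1, seed=3, mutation=mut)
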