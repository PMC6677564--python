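"""Approximate Bayesian computation over the four demographic scenarios.

Workflow: simulate a reference table of (scenario, parameters, summary
statistics) from the priors; standardize statistics by the table's
median/MAD; choose among scenarios by the rejection (direct) estimate on the
``k_direct`` closest rows and by multinomial logistic regression on the
``k_logistic`` closest rows; estimate the winning scenario's parameters with
the local-linear (Beaumont) regression adjustment under a logit transform to
the prior bounds; measure confidence in the choice with pseudo-observed
datasets (prior-drawn, or conditioned on fixed parameters); and check model
fit by simulating from the posterior.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent_gsm import (
    ALL_PARAMS,
    MutationModel,
    PriorSpec,
    ScenarioSpec,
    sample_prior,
    simulate_stats_batch,
)
from .datatypes import LocusMeta

STAT_NAMES = ["mean_A", "mean_GD", "mean_size_var", "mean_M"]


@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, statistics) rows plus normalization."""

    scenario_ids: np.ndarray           # (n,)
    params: pd.DataFrame               # (n, all params), NaN where irrelevant
    stats: np.ndarray                  # (n, 4)
    stat_names: list[str]
    medians: np.ndarray
    mads: np.ndarray
    seed: int
    dropped_stats: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.scenario_ids)

    def scenarios(self) -> np.ndarray:
        return np.unique(self.scenario_ids)

    def normalize(self, stats: np.ndarray) -> np.ndarray:
        """Median/MAD standardization, dropping zero-spread statistics."""
        keep = self.mads > 0
        return (np.atleast_2d(stats)[:, keep] - self.medians[keep]) / self.mads[keep]

    def distances(self, obs: np.ndarray) -> np.ndarray:
        z = self.normalize(self.stats)
        zo = self.normalize(obs)[0]
        return np.sqrt(((z - zo) ** 2).sum(axis=1))

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            scenario_ids=self.scenario_ids,
            params=self.params.to_numpy(),
            param_names=np.array(self.params.columns, dtype=object),
            stats=self.stats,
            medians=self.medians,
            mads=self.mads,
            seed=self.seed,
        )

    @classmethod
    def load(cls, path) -> "ReferenceTable":
        z = np.load(path, allow_pickle=True)
        medians, mads = z["medians"], z["mads"]
        return cls(
            scenario_ids=z["scenario_ids"],
            params=pd.DataFrame(z["params"], columns=list(z["param_names"])),
            stats=z["stats"],
            stat_names=list(STAT_NAMES),
            medians=medians,
            mads=mads,
            seed=int(z["seed"]),
            dropped_stats=[n for n, m in zip(STAT_NAMES, mads) if m == 0],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = self.params.copy()
        df.insert(0, "scenario", self.scenario_ids)
        for i, name in enumerate(self.stat_names):
            df[name] = self.stats[:, i]
        return df


def build_reference_table(
    scenarios,
    priors: PriorSpec,
    panel: list[LocusMeta],
    n_ind: int,
    n_per_scenario: int,
    seed: int,
    mutation: MutationModel | None = None,
    chunk_size: int = 20_000,
) -> ReferenceTable:
    """Simulate the reference table, ``n_per_scenario`` rows per scenario.

    Deterministic under ``seed`` (single process); generation is chunked so
    memory stays flat for large tables. Statistics with zero spread (MAD = 0)
    are recorded and excluded from distances.
    """
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    mutation = mutation or MutationModel()
    scenario_ids: list[np.ndarray] = []
    all_params: list[pd.DataFrame] = []
    all_stats: list[np.ndarray] = []
    rng = np.random.default_rng(seed)
    for sid in scenarios:
        spec = ScenarioSpec(int(sid))
        done = 0
        while done < n_per_scenario:
            m = min(chunk_size, n_per_scenario - done)
            draws = [sample_prior(priors, spec.scenario_id, rng) for _ in range(m)]
            stats = simulate_stats_batch(spec, draws, panel, n_ind, rng, mutation)
            block = pd.DataFrame(np.nan, index=range(m), columns=ALL_PARAMS)
            for name in spec.param_names:
                block[name] = [d[name] for d in draws]
            scenario_ids.append(np.full(m, spec.scenario_id))
            all_params.append(block)
            all_stats.append(stats)
            done += m
    stats = np.vstack(all_stats)
    if not np.isfinite(stats).all():
        raise RuntimeError("non-finite summary statistics in reference table")
    medians = np.median(stats, axis=0)
    mads = np.median(np.abs(stats - medians), axis=0)
    dropped = [n for n, m in zip(STAT_NAMES, mads) if m == 0]
    if dropped:
        warnings.warn(f"zero-spread statistics excluded from distance: {dropped}")
    return ReferenceTable(
        scenario_ids=np.concatenate(scenario_ids),
        params=pd.concat(all_params, ignore_index=True),
        stats=stats,
        stat_names=list(STAT_NAMES),
        medians=medians,
        mads=mads,
        seed=seed,
        dropped_stats=dropped,
    )


# ---------------------------------------------------------------------------
# model choice
# ---------------------------------------------------------------------------

@dataclass
class ModelChoiceResult:
    scenarios: np.ndarray
    direct: pd.Series | None = None
    logistic: pd.Series | None = None
    logistic_ci: pd.DataFrame | None = None
    flags: list[str] = field(default_factory=list)

    def best(self, method: str = "logistic") -> int:
        probs = getattr(self, method)
        if probs is None:
            probs = self.direct if self.logistic is None else self.logistic
        return int(probs.idxmax())


def model_choice_direct(
    obs: np.ndarray, rt: ReferenceTable, k_direct: int = 500
) -> ModelChoiceResult:
    """Rejection estimate: scenario frequencies among the k closest rows."""
    if k_direct > rt.n_rows:
        raise ValueError("k_direct exceeds the reference table size")
    d = rt.distances(obs)
    idx = np.argpartition(d, k_direct - 1)[:k_direct]
    sids = rt.scenario_ids[idx]
    scen = rt.scenarios()
    probs = pd.Series(
        [(sids == s).mean() for s in scen], index=scen, name="direct"
    )
    return ModelChoiceResult(scenarios=scen, direct=probs)


def _softmax_probs_and_ci(x0, beta, cov, classes):
    """Delta-method 95 % CI for multinomial-logit class probabilities at x0."""
    K = len(classes)
    d = len(x0)
    eta = np.concatenate([[0.0], beta @ x0])  # (K,)
    e = np.exp(eta - eta.max())
    p = e / e.sum()
    # gradient of p_k wrt vec(beta) [(K-1) * d, column-major by class]
    grads = np.zeros((K, (K - 1) * d))
    for k in range(K):
        for j in range(1, K):
            dpk_detaj = p[k] * ((1.0 if j == k else 0.0) - p[j])
            grads[k, (j - 1) * d : j * d] = dpk_detaj * x0
    var = np.einsum("ki,ij,kj->k", grads, cov, grads)
    half = 1.96 * np.sqrt(np.maximum(var, 0.0))
    return p, np.clip(p - half, 0, 1), np.clip(p + half, 0, 1)


def model_choice_logistic(
    obs: np.ndarray, rt: ReferenceTable, k_logistic: int = 40_000
) -> ModelChoiceResult:
    """Multinomial logistic regression of scenario on standardized statistics
    over the k closest rows, evaluated at the observed statistics.

    95 % CIs come from the estimator's asymptotic covariance (delta method);
    on separation or non-convergence, an L2-regularized fit is used and
    flagged (no CIs).
    """
    if k_logistic > rt.n_rows:
        raise ValueError("k_logistic exceeds the reference table size")
    d = rt.distances(obs)
    idx = np.argpartition(d, k_logistic - 1)[:k_logistic]
    z = rt.normalize(rt.stats[idx])
    y = rt.scenario_ids[idx]
    classes = np.unique(y)
    scen = rt.scenarios()
    if len(classes) < 2:
        probs = pd.Series((scen == classes[0]).astype(float), index=scen)
        return ModelChoiceResult(
            scenarios=scen, logistic=probs, flags=["single scenario among k best"]
        )
    X = np.column_stack([np.ones(len(z)), z])
    x0 = np.concatenate([[1.0], rt.normalize(obs)[0]])
    flags: list[str] = []
    try:
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MNLogit(pd.Categorical(y).codes, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", False):
            raise RuntimeError("MNLogit did not converge")
        beta = np.asarray(fit.params).T  # (K-1, d)
        cov = np.asarray(fit.cov_params())
        p, lo, hi = _softmax_probs_and_ci(x0, beta, cov, classes)
        if not np.isfinite(p).all():
            raise RuntimeError("non-finite probabilities (quasi-separation)")
        if not np.isfinite(lo).all() or not np.isfinite(hi).all():
            lo = np.full_like(p, np.nan)
            hi = np.full_like(p, np.nan)
        probs = pd.Series(0.0, index=scen)
        ci = pd.DataFrame(np.nan, index=scen, columns=["low", "high"])
        for c, pk, l, h in zip(classes, p, lo, hi):
            probs[c] = pk
            ci.loc[c] = [l, h]
        return ModelChoiceResult(scenarios=scen, logistic=probs, logistic_ci=ci)
    except Exception as exc:  # separation, singularity, non-convergence
        flags.append(f"regularized fallback: {exc}")
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(max_iter=1000).fit(z, y)
        p = clf.predict_proba(rt.normalize(obs))[0]
        probs = pd.Series(0.0, index=scen)
        for c, pk in zip(clf.classes_, p):
            probs[c] = pk
        return ModelChoiceResult(scenarios=scen, logistic=probs, flags=flags)


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

@dataclass
class ParamPosterior:
    param_names: list[str]
    samples: pd.DataFrame   # adjusted draws (k, params)
    weights: np.ndarray
    mode: pd.Series
    q050: pd.Series
    q950: pd.Series
    adjusted: bool = True
    flags: list[str] = field(default_factory=list)

    def draw(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        w = self.weights / self.weights.sum()
        idx = rng.choice(len(self.samples), size=n, p=w)
        return self.samples.iloc[idx].reset_index(drop=True)


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return float(np.interp(q, cw, x))


def _weighted_kde_mode(x: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    mu = (w * x).sum()
    sd = np.sqrt(max((w * (x - mu) ** 2).sum(), 1e-300))
    n_eff = 1.0 / (w**2).sum()
    bw = 1.06 * sd * n_eff ** (-0.2)
    if bw <= 0 or not np.isfinite(bw):
        return float(x[np.argmax(w)])
    grid = np.linspace(x.min(), x.max(), 512)
    dens = np.zeros_like(grid)
    for xi, wi in zip(x, w):
        dens += wi * np.exp(-0.5 * ((grid - xi) / bw) ** 2)
    return float(grid[np.argmax(dens)])


def estimate_parameters(
    obs: np.ndarray,
    rt: ReferenceTable,
    scenario_id: int,
    priors: PriorSpec,
    k_est: int = 20_000,
) -> ParamPosterior:
    """Local-linear regression-adjusted posterior for one scenario's parameters.

    The k closest rows of that scenario are accepted with Epanechnikov
    weights; parameters are logit-transformed to their prior bounds,
    regressed on the standardized statistics and adjusted to the observed
    point, then back-transformed. Mode from a weighted Gaussian KDE
    (Silverman bandwidth) on the natural scale; q050/q950 are weighted
    quantiles. A singular design falls back to the unadjusted rejection
    posterior (flagged).
    """
    mask = rt.scenario_ids == scenario_id
    if not mask.any():
        raise ValueError(f"scenario {scenario_id} absent from reference table")
    sub_stats = rt.stats[mask]
    spec = ScenarioSpec(int(scenario_id))
    names = spec.param_names
    sub_params = rt.params.loc[mask, names].to_numpy()
    k_est = min(k_est, mask.sum())
    z = rt.normalize(sub_stats)
    zo = rt.normalize(obs)[0]
    d = np.sqrt(((z - zo) ** 2).sum(axis=1))
    idx = np.argsort(d)[:k_est]
    d_acc = d[idx]
    delta = d_acc.max()
    w = (
        np.ones_like(d_acc)
        if delta == 0
        else np.maximum(1.0 - (d_acc / delta) ** 2, 0.0)
    )
    if w.sum() <= 0 or np.count_nonzero(w) < 2:
        w = np.ones_like(d_acc)  # all accepted rows at equal distance
    theta = sub_params[idx]
    X = z[idx] - zo  # centred at the observation

    flags: list[str] = []
    eps = 1e-9
    trans = np.empty_like(theta)
    bounds = [priors.bounds[n] for n in names]
    for j, (lo, hi) in enumerate(bounds):
        x = np.clip(theta[:, j], lo + eps * (hi - lo), hi - eps * (hi - lo))
        trans[:, j] = np.log((x - lo) / (hi - x))

    spread = X.std(axis=0)
    adjusted = True
    if (spread <= 1e-12).all():
        adj = trans  # no-information limit: keep the rejection posterior
        adjusted = False
    else:
        design = np.column_stack([np.ones(len(X)), X])
        sw = np.sqrt(w)
        try:
            coef, _, rank, _ = np.linalg.lstsq(
                design * sw[:, None], trans * sw[:, None], rcond=None
            )
            if rank < design.shape[1]:
                flags.append("singular local-linear design; unadjusted posterior")
                adj = trans
                adjusted = False
            else:
                # theta* = alpha + residuals = theta - beta (s - s_obs)
                adj = trans - X @ coef[1:]
        except np.linalg.LinAlgError:
            flags.append("local-linear solve failed; unadjusted posterior")
            adj = trans
            adjusted = False

    back = np.empty_like(adj)
    for j, (lo, hi) in enumerate(bounds):
        back[:, j] = lo + (hi - lo) / (1.0 + np.exp(-adj[:, j]))

    samples = pd.DataFrame(back, columns=names)
    mode = pd.Series(
        {n: _weighted_kde_mode(back[:, j], w) for j, n in enumerate(names)}
    )
    q050 = pd.Series(
        {n: _weighted_quantile(back[:, j], w, 0.05) for j, n in enumerate(names)}
    )
    q950 = pd.Series(
        {n: _weighted_quantile(back[:, j], w, 0.95) for j, n in enumerate(names)}
    )
    return ParamPosterior(
        param_names=names, samples=samples, weights=w,
        mode=mode, q050=q050, q950=q950, adjusted=adjusted, flags=flags,
    )


# ---------------------------------------------------------------------------
# confidence in scenario choice & model checking
# ---------------------------------------------------------------------------

def predictive_error(
    priors: PriorSpec,
    rt: ReferenceTable,
    panel: list[LocusMeta],
    n_ind: int,
    n_pods: int,
    seed: int,
    mutation: MutationModel | None = None,
    method: str = "direct",
    k: int | None = None,
    scenario_params: dict[int, dict[str, float]] | None = None,
) -> tuple[float, pd.Series]:
    """Misclassification rate of scenario choice on pseudo-observed datasets.

    Pods cycle through the table's scenarios; parameters come from the priors
    (default, the prior-based confidence measure) or, when
    ``scenario_params`` supplies fixed values, from those (the
    posterior-conditioned variant). Returns (overall error, per-scenario
    error).
    """
    if n_pods < 1:
        raise ValueError("n_pods must be >= 1")
    mutation = mutation or MutationModel()
    rng = np.random.default_rng(seed)
    scen = rt.scenarios()
    if scenario_params is not None:
        scen = np.array(sorted(scenario_params))
    truths = np.array([scen[i % len(scen)] for i in range(n_pods)])
    wrong = 0
    per = {int(s): [0, 0] for s in scen}
    if k is None:
        k = 500 if method == "direct" else min(40_000, rt.n_rows)
    for true_sid in truths:
        spec = ScenarioSpec(int(true_sid))
        if scenario_params is not None:
            params = dict(scenario_params[int(true_sid)])
        else:
            params = sample_prior(priors, int(true_sid), rng)
        stats = simulate_stats_batch(spec, [params], panel, n_ind, rng, mutation)[0]
        if method == "direct":
            res = model_choice_direct(stats, rt, k_direct=k)
            chosen = res.best("direct")
        else:
            res = model_choice_logistic(stats, rt, k_logistic=k)
            chosen = res.best("logistic")
        per[int(true_sid)][1] += 1
        if chosen != int(true_sid):
            wrong += 1
            per[int(true_sid)][0] += 1
    per_scen = pd.Series(
        {s: (w / n if n else np.nan) for s, (w, n) in per.items()}, name="error"
    )
    return wrong / n_pods, per_scen


def posterior_model_check(
    obs: np.ndarray,
    scenario_id: int,
    posterior: ParamPosterior,
    panel: list[LocusMeta],
    n_ind: int,
    n_ppc: int,
    seed: int,
    mutation: MutationModel | None = None,
) -> pd.DataFrame:
    """Posterior predictive tail probabilities P(sim <= obs) per statistic.

    Statistics with tail probability below 0.025 or above 0.975 are flagged
    as poorly fit. With ``n_ppc = 1`` the probabilities are degenerate (0/1)
    and a warning is raised.
    """
    if n_ppc < 1:
        raise ValueError("n_ppc must be >= 1")
    if n_ppc == 1:
        warnings.warn("n_ppc=1 gives degenerate 0/1 tail probabilities")
    rng = np.random.default_rng(seed)
    draws_df = posterior.draw(n_ppc, rng)
    spec = ScenarioSpec(int(scenario_id))
    draws = [dict(row) for _, row in draws_df.iterrows()]
    sims = simulate_stats_batch(
        spec, draws, panel, n_ind, rng, mutation or MutationModel()
    )
    obs = np.asarray(obs, dtype=float)
    rows = []
    for i, name in enumerate(STAT_NAMES):
        tail = float((sims[:, i] <= obs[i]).mean())
        rows.append(
            {"statistic": name, "tail_prob": tail, "poor_fit": tail < 0.025 or tail > 0.975}
        )
    return pd.DataFrame(rows).set_index("statistic")
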