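"""Single-population coalescent simulation of microsatellites under a
generalized stepwise mutation model (GSM).

Four single-population demographic scenarios are supported, indexed as in the
model-choice analysis:

1. constant size ``Ne``;
2. population still in a bottleneck: current ``Ne2``, ancestral ``Na2 > Ne2``
   before generation ``t`` (backwards in time);
3. population expanded out of a bottleneck: current ``Ne3 > Na3``, the small
   ``Na3`` before ``t``;
4. transitory bottleneck: current ``Ne4``, size ``Nb`` between ``t1`` and
   ``t2`` (``t1 < t2``), ancestral ``Na4`` before ``t2``; ``Nb`` below both.

Genealogies follow the continuous-time Kingman coalescent with
piecewise-constant diploid size (pairwise coalescence rate 1/(2N) per
generation), with exact exponential rescaling at epoch boundaries. Each
mutation moves the allele by ±(1 + G) repeat units with
G ~ Geometric(P) on {0, 1, 2, ...} and equiprobable sign; alleles are
reflected at the locus allele-range boundaries (truncation by clamping is
available as an option). Per-locus mutation rates are hierarchical: a mean
rate drawn uniformly, per-locus rates Gamma-distributed (shape 2) around it
and truncated by rejection.

The four model-choice summary statistics are the across-locus means of the
number of alleles, unbiased gene diversity, allele-size variance (repeat
units, denominator n) and the Garza–Williamson M = k/(r + 1).

Hot loops are numba-jitted when numba is importable and fall back to the
identical pure-Python code otherwise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatypes import MISSING, GenotypeMatrix, LocusMeta

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


SCENARIO_PARAMS: dict[int, list[str]] = {
    1: ["Ne"],
    2: ["Ne2", "Na2", "t"],
    3: ["Ne3", "Na3", "t"],
    4: ["Ne4", "Nb", "Na4", "t1", "t2"],
}

ALL_PARAMS = sorted({p for ps in SCENARIO_PARAMS.values() for p in ps})


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the four demographic histories, with its parameter symbols."""

    scenario_id: int

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIO_PARAMS:
            raise ValueError(f"unknown scenario {self.scenario_id}")

    @property
    def param_names(self) -> list[str]:
        return SCENARIO_PARAMS[self.scenario_id]

    def epochs(self, params: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
        """(start_times, sizes) backwards in time; the last epoch is open-ended."""
        s = self.scenario_id
        if s == 1:
            starts, sizes = [0.0], [params["Ne"]]
        elif s == 2:
            starts, sizes = [0.0, params["t"]], [params["Ne2"], params["Na2"]]
        elif s == 3:
            starts, sizes = [0.0, params["t"]], [params["Ne3"], params["Na3"]]
        else:
            starts = [0.0, params["t1"], params["t2"]]
            sizes = [params["Ne4"], params["Nb"], params["Na4"]]
        if any(n < 2 for n in sizes):
            raise ValueError("effective sizes must be >= 2")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must increase")
        return np.asarray(starts, dtype=float), np.asarray(sizes, dtype=float)

    def satisfies_constraints(self, params: dict[str, float]) -> bool:
        s = self.scenario_id
        if s == 2:
            return params["Ne2"] < params["Na2"]
        if s == 3:
            return params["Ne3"] > params["Na3"]
        if s == 4:
            return (
                params["Nb"] < params["Ne4"]
                and params["Nb"] < params["Na4"]
                and params["t1"] < params["t2"]
            )
        return True


#: Default uniform prior bounds. Size priors are deliberately broad; times
#: are in generations (one generation per year for these annual herbs).
DEFAULT_PRIOR_BOUNDS: dict[str, tuple[float, float]] = {
    **{p: (10.0, 500_000.0) for p in ALL_PARAMS if p.startswith(("N", "n"))},
    "t": (10.0, 50_000.0),
    "t1": (10.0, 50_000.0),
    "t2": (10.0, 50_000.0),
}


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior bounds per demographic parameter, with ordering constraints."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PRIOR_BOUNDS)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi and lo != hi:
                raise ValueError(f"prior for {name}: min must be <= max")


def sample_prior(
    ps: PriorSpec, scenario_id: int, rng: np.random.Generator, max_tries: int = 10_000
) -> dict[str, float]:
    """One draw from the joint prior, rejection-sampled to the constraints."""
    spec = ScenarioSpec(scenario_id)
    for _ in range(max_tries):
        draw = {
            name: float(rng.uniform(*ps.bounds[name])) for name in spec.param_names
        }
        if spec.satisfies_constraints(draw):
            return draw
    raise RuntimeError("prior constraints rejected every draw; check bounds")


@dataclass(frozen=True)
class MutationModel:
    """Hierarchical GSM mutation prior.

    The dataset-level mean rate is Uniform(*mu_mean_bounds*); per-locus rates
    are Gamma(shape, mean=mean rate), redrawn by rejection into
    *locus_rate_bounds*. The geometric parameter P of the step-size law is
    drawn per locus from Uniform(*p_gsm_bounds*); P -> 1 recovers the strict
    single-step model. The default P range [0.1, 0.3] is the usual empirical
    band for microsatellite step-size fits (and the DIYABC default).
    """

    mu_mean_bounds: tuple[float, float] = (1e-4, 1e-2)
    locus_rate_bounds: tuple[float, float] = (1e-5, 1e-2)
    gamma_shape: float = 2.0
    p_gsm_bounds: tuple[float, float] = (0.1, 0.3)

    def draw(self, n_loci: int, rng: np.random.Generator):
        """(per-locus rates, per-locus P, mean rate) for one simulated dataset."""
        mu_bar = rng.uniform(*self.mu_mean_bounds)
        lo, hi = self.locus_rate_bounds
        rates = np.empty(n_loci)
        for j in range(n_loci):
            while True:
                r = rng.gamma(self.gamma_shape, mu_bar / self.gamma_shape)
                if lo <= r <= hi:
                    rates[j] = r
                    break
        p_lo, p_hi = self.p_gsm_bounds
        ps = rng.uniform(max(p_lo, 1e-6), p_hi, size=n_loci)
        return rates, ps, mu_bar


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

@njit(cache=False)
def _coalesce(n_genes, starts, sizes, seed):
    """Kingman coalescent with piecewise-constant N.

    Returns (parent, node_time): 2*n_genes-1 nodes, tips 0..n-1 at time 0,
    internal nodes in coalescence order, root last. Times in generations.
    """
    np.random.seed(seed)
    n_nodes = 2 * n_genes - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    active = np.empty(n_genes, dtype=np.int64)
    for i in range(n_genes):
        active[i] = i
    k = n_genes
    t = 0.0
    e = 0
    n_epochs = len(starts)
    nxt = n_genes
    while k > 1:
        remaining = -math.log(np.random.random())
        while True:
            rate = (k * (k - 1) / 2.0) / (2.0 * sizes[e])
            if e + 1 < n_epochs:
                cap = starts[e + 1] - t
                if remaining > rate * cap:
                    remaining -= rate * cap
                    t = starts[e + 1]
                    e += 1
                    continue
            t += remaining / rate
            break
        i = np.random.randint(0, k)
        j = np.random.randint(0, k - 1)
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = nxt
        parent[b] = nxt
        node_time[nxt] = t
        lo_idx = min(i, j)
        hi_idx = max(i, j)
        active[lo_idx] = nxt
        active[hi_idx] = active[k - 1]
        nxt += 1
        k -= 1
    return parent, node_time


@njit(cache=False)
def _reflect(v, lo, hi):
    # closed-form fold into [lo, hi] (period 2*(hi-lo) triangular wave)
    width = hi - lo
    period = 2 * width
    u = (v - lo) % period
    if u > width:
        u = period - u
    return lo + u


@njit(cache=False)
def _negbin_geom0_sum(k, p_gsm):
    """Sum of k i.i.d. Geometric(p) variables on {0,1,...} (gamma-Poisson mix)."""
    if k == 0 or p_gsm >= 1.0:
        return np.int64(0)
    lam = np.random.gamma(k, (1.0 - p_gsm) / p_gsm)
    return np.int64(np.random.poisson(lam))


@njit(cache=False)
def _branch_displacement(m, p_gsm):
    """Net allele-size change from m GSM mutations (signed steps of 1 + G)."""
    if m == 0:
        return np.int64(0)
    m_plus = np.random.binomial(m, 0.5)
    m_minus = m - m_plus
    return (
        np.int64(2 * m_plus - m)
        + _negbin_geom0_sum(m_plus, p_gsm)
        - _negbin_geom0_sum(m_minus, p_gsm)
    )


@njit(cache=False)
def _drop_mutations(parent, node_time, n_genes, rate, p_gsm, root_allele, lo, hi, clamp):
    """GSM mutations along branches, root to tips; returns tip allele sizes.

    With the reflecting boundary (default) the walk is sampled as the
    triangular fold of the free walk: per branch only the net displacement is
    drawn (a difference of negative binomials), and node values are folded
    into [lo, hi]. Because each mutation's sign is equiprobable, this equals
    the event-by-event reflected walk in joint distribution across the tree.
    Clamping is an absorbing boundary, so that mode keeps the event loop.
    """
    n_nodes = 2 * n_genes - 1
    allele = np.empty(n_nodes, dtype=np.int64)
    allele[n_nodes - 1] = root_allele
    for v in range(n_nodes - 2, -1, -1):
        length = node_time[parent[v]] - node_time[v]
        m = np.random.poisson(rate * length)
        if clamp:
            val = allele[parent[v]]
            for _ in range(m):
                if p_gsm >= 1.0:
                    step = np.int64(1)
                else:
                    step = np.int64(1) + _negbin_geom0_sum(1, p_gsm)
                if np.random.random() < 0.5:
                    step = -step
                val = min(max(val + step, lo), hi)
            allele[v] = val
        else:
            allele[v] = allele[parent[v]] + _branch_displacement(m, p_gsm)
    if not clamp:
        for i in range(n_genes):
            allele[i] = _reflect(allele[i], lo, hi)
    return allele[:n_genes]


@njit(cache=False)
def _tip_stats(tips, lo, hi):
    """(A, unbiased GD, size variance, M) from one locus's gene-copy sizes."""
    n = tips.shape[0]
    x = np.sort(tips)
    k = 1
    run = 1
    ssq = 0.0
    for i in range(1, n):
        if x[i] == x[i - 1]:
            run += 1
        else:
            ssq += run * run
            k += 1
            run = 1
    ssq += run * run
    gd = n * (1.0 - ssq / (n * n)) / (n - 1.0)
    mean = 0.0
    for i in range(n):
        mean += x[i]
    mean /= n
    var = 0.0
    for i in range(n):
        var += (x[i] - mean) ** 2
    var /= n
    m = k / (x[n - 1] - x[0] + 1.0)
    return k, gd, var, m


@njit(cache=False)
def _stats_batch(starts, sizes, n_epochs, rates, ps, roots, los, his, n_genes, seeds, clamp):
    """Summary-statistic vectors for a batch of simulated datasets.

    starts/sizes: (nsims, max_epochs); rates/ps: (nsims, nloci);
    seeds: (nsims, nloci). Returns (nsims, 4).
    """
    nsims, nloci = rates.shape
    out = np.empty((nsims, 4))
    for s in range(nsims):
        acc = np.zeros(4)
        for l in range(nloci):
            parent, node_time = _coalesce(
                n_genes, starts[s, : n_epochs[s]], sizes[s, : n_epochs[s]], seeds[s, l]
            )
            tips = _drop_mutations(
                parent, node_time, n_genes, rates[s, l], ps[s, l],
                roots[l], los[l], his[l], clamp,
            )
            a, gd, var, m = _tip_stats(tips, los[l], his[l])
            acc[0] += a
            acc[1] += gd
            acc[2] += var
            acc[3] += m
        for q in range(4):
            out[s, q] = acc[q] / nloci
    return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_genealogy(
    scenario: ScenarioSpec,
    params: dict[str, float],
    n_genes: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one coalescent tree; returns (parent, node_times)."""
    if n_genes < 2:
        raise ValueError("need at least two gene copies")
    starts, sizes = scenario.epochs(params)
    seed = int(rng.integers(2**31 - 1))
    return _coalesce(n_genes, starts, sizes, seed)


def mutate_gsm(
    tree: tuple[np.ndarray, np.ndarray],
    locus: LocusMeta,
    rate: float,
    p_gsm: float,
    rng: np.random.Generator,
    boundary: str = "reflect",
) -> np.ndarray:
    """Evolve allele sizes down a genealogy; returns tip alleles (repeat units)."""
    parent, node_time = tree
    n_genes = (len(parent) + 1) // 2
    lo, hi = locus.allele_range
    root = (lo + hi) // 2
    _seed_kernel(int(rng.integers(2**31 - 1)))
    return _drop_mutations(
        parent, node_time, n_genes, rate, p_gsm, root, lo, hi, boundary == "clamp"
    )


@njit(cache=False)
def _seed_kernel(seed):
    np.random.seed(seed)


def simulate_dataset(
    scenario: ScenarioSpec,
    params: dict[str, float],
    panel: Sequence[LocusMeta],
    n_ind: int,
    rng: np.random.Generator,
    mutation: MutationModel | None = None,
    rates: np.ndarray | None = None,
    p_gsm: np.ndarray | None = None,
    boundary: str = "reflect",
) -> GenotypeMatrix:
    """Simulate a diploid genotype matrix: one independent genealogy per locus,
    2*n_ind gene copies, genotypes formed by pairing consecutive copies
    (tips are exchangeable, so this is a uniform random pairing)."""
    if not panel:
        raise ValueError("empty locus panel")
    if rates is None or p_gsm is None:
        rates, p_gsm, _ = (mutation or MutationModel()).draw(len(panel), rng)
    calls = np.empty((n_ind, len(panel), 2), dtype=np.int64)
    for j, meta in enumerate(panel):
        tree = simulate_genealogy(scenario, params, 2 * n_ind, rng)
        tips = mutate_gsm(tree, meta, float(rates[j]), float(p_gsm[j]), rng, boundary)
        calls[:, j, 0] = tips[0::2]
        calls[:, j, 1] = tips[1::2]
    inds = [f"sim{i + 1}" for i in range(n_ind)]
    return GenotypeMatrix(inds, list(panel), calls)


def summary_stats(g: GenotypeMatrix) -> np.ndarray:
    """(mean_A, mean_GD, mean allele-size variance, mean_M) across loci.

    Computed at the gene-copy level with missing calls excluded; loci with
    fewer than two observed gene copies are skipped.
    """
    acc = np.zeros(4)
    n_used = 0
    for j, meta in enumerate(g.loci):
        col = g.calls[:, j, :]
        tips = col[col != MISSING].astype(np.int64)
        if tips.size < 2:
            continue
        lo, hi = meta.allele_range
        a, gd, var, m = _tip_stats(np.ascontiguousarray(tips), lo, hi)
        acc += (a, gd, var, m)
        n_used += 1
    if n_used == 0:
        raise ValueError("no locus with >= 2 gene copies")
    return acc / n_used


def simulate_stats_batch(
    scenario: ScenarioSpec,
    param_draws: list[dict[str, float]],
    panel: Sequence[LocusMeta],
    n_ind: int,
    rng: np.random.Generator,
    mutation: MutationModel | None = None,
    boundary: str = "reflect",
) -> np.ndarray:
    """Summary statistics for many parameter draws under one scenario.

    The per-dataset mutation rates and GSM parameters are drawn here
    (hierarchical model). Returns an (n_draws, 4) array in the order
    (mean_A, mean_GD, mean_size_var, mean_M).
    """
    mutation = mutation or MutationModel()
    nsims = len(param_draws)
    nloci = len(panel)
    max_e = 3
    starts = np.zeros((nsims, max_e))
    sizes = np.ones((nsims, max_e))
    n_epochs = np.empty(nsims, dtype=np.int64)
    rates = np.empty((nsims, nloci))
    ps = np.empty((nsims, nloci))
    for s, draw in enumerate(param_draws):
        st, sz = scenario.epochs(draw)
        n_epochs[s] = len(st)
        starts[s, : len(st)] = st
        sizes[s, : len(sz)] = sz
        rates[s], ps[s], _ = mutation.draw(nloci, rng)
    roots = np.array([(m.allele_range[0] + m.allele_range[1]) // 2 for m in panel])
    los = np.array([m.allele_range[0] for m in panel])
    his = np.array([m.allele_range[1] for m in panel])
    seeds = rng.integers(2**31 - 1, size=(nsims, nloci))
    return _stats_batch(
        starts, sizes, n_epochs, rates, ps, roots, los, his,
        2 * n_ind, seeds, boundary == "clamp",
    )
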