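"""Partitioning genetic variation among populations: AMOVA, F_ST, DAPC.

The AMOVA is the two-level (among / within populations) decomposition of
squared inter-individual distances, locus by locus, with the
number-of-different-alleles distance (an F_ST analogue; squared allele-size
difference gives an R_ST analogue via ``distance="size"``). Significance is
assessed by permuting whole individuals across populations. Pairwise F_ST
values are two-population AMOVAs. DAPC reduces centred allele-dosage vectors
by PCA, optionally infers the number of groups by Gaussian-mixture BIC on
the PC scores, and ordinates with linear discriminant analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .datatypes import MISSING, GenotypeMatrix, PopulationMap

__all__ = ["AmovaResult", "DapcResult", "amova", "pairwise_fst", "dapc"]


@dataclass
class AmovaResult:
    sigma_among: float
    sigma_within: float
    percent_among: float
    percent_within: float
    fst: float
    p_value: float
    n_permutations: int
    per_locus: pd.DataFrame
    excluded_populations: list[str] = field(default_factory=list)


def _pair_distance_matrix(calls: np.ndarray, distance: str) -> np.ndarray:
    """Squared distances between all individuals at one locus.

    ``allele``: number of allele differences under best matching (0, 1, 2);
    ``size``: summed squared repeat-count differences under best matching.
    Missing genotypes yield NaN rows/columns.
    """
    n = calls.shape[0]
    a, b = calls[:, 0].astype(float), calls[:, 1].astype(float)
    a = np.where(calls[:, 0] == MISSING, np.nan, a)
    b = np.where(calls[:, 0] == MISSING, np.nan, b)
    if distance == "allele":
        m1 = (a[:, None] != a[None, :]).astype(float) + (
            b[:, None] != b[None, :]
        ).astype(float)
        m2 = (a[:, None] != b[None, :]).astype(float) + (
            b[:, None] != a[None, :]
        ).astype(float)
        d = np.minimum(m1, m2)
    elif distance == "size":
        m1 = (a[:, None] - a[None, :]) ** 2 + (b[:, None] - b[None, :]) ** 2
        m2 = (a[:, None] - b[None, :]) ** 2 + (b[:, None] - a[None, :]) ** 2
        d = np.minimum(m1, m2)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    bad = np.isnan(a)
    d[bad, :] = np.nan
    d[:, bad] = np.nan
    np.fill_diagonal(d, 0.0)
    return d


def _locus_components(d: np.ndarray, labels: np.ndarray, valid: np.ndarray):
    """(sigma_a, sigma_w, ss_among, ss_within) for one locus distance matrix."""
    d = d[np.ix_(valid, valid)]
    labels = labels[valid]
    groups, sizes = np.unique(labels, return_counts=True)
    keep = sizes >= 1
    N = len(labels)
    G = (sizes > 0).sum()
    if N < 2 or G < 2 or N - G < 1:
        return np.nan, np.nan, np.nan, np.nan
    ss_total = np.triu(d, 1).sum() / N
    ss_within = 0.0
    for gname, size in zip(groups, sizes):
        idx = labels == gname
        ss_within += np.triu(d[np.ix_(idx, idx)], 1).sum() / size
    ss_among = ss_total - ss_within
    df_a, df_w = G - 1, N - G
    sigma_w = ss_within / df_w
    n_prime = (N - (sizes**2).sum() / N) / df_a
    sigma_a = (ss_among / df_a - sigma_w) / n_prime
    return sigma_a, sigma_w, ss_among, ss_within


def _fst_from_matrices(mats, valids, labels: np.ndarray):
    comps = [_locus_components(d, labels, v) for d, v in zip(mats, valids)]
    sa = np.nansum([c[0] for c in comps])
    sw = np.nansum([c[1] for c in comps])
    total = sa + sw
    return (sa / total if total > 0 else np.nan), comps


def amova(
    g: GenotypeMatrix,
    pops: PopulationMap,
    n_perm: int = 10_000,
    seed: int = 0,
    distance: str = "allele",
) -> AmovaResult:
    """Two-level locus-by-locus AMOVA with whole-individual permutation test.

    Populations with a single individual are excluded (with a record in the
    result); variance components are summed over loci and F_ST (Phi_ST) is
    their ratio. Negative components are retained as computed.
    """
    labels = pops.labels_for(g)
    names = pops.populations()
    sizes = np.bincount(labels, minlength=len(names))
    excluded = [names[p] for p in range(len(names)) if 0 < sizes[p] < 2]
    keep_ind = np.flatnonzero(~np.isin(labels, [names.index(e) for e in excluded]))
    if excluded:
        g = g.subset_individuals(keep_ind)
        labels = labels[keep_ind]
    if len(np.unique(labels)) < 2:
        raise ValueError("AMOVA needs at least two populations with >= 2 individuals")

    mats = [
        _pair_distance_matrix(g.calls[:, j, :], distance) for j in range(g.n_loci)
    ]
    valids = [g.calls[:, j, 0] != MISSING for j in range(g.n_loci)]
    fst_obs, comps = _fst_from_matrices(mats, valids, labels)
    sa = np.nansum([c[0] for c in comps])
    sw = np.nansum([c[1] for c in comps])
    total = sa + sw
    per_locus = pd.DataFrame(
        comps, index=g.locus_names,
        columns=["sigma_among", "sigma_within", "ss_among", "ss_within"],
    )

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        fst_perm, _ = _fst_from_matrices(mats, valids, perm)
        if fst_perm >= fst_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return AmovaResult(
        sigma_among=float(sa),
        sigma_within=float(sw),
        percent_among=float(100.0 * sa / total),
        percent_within=float(100.0 * sw / total),
        fst=float(fst_obs),
        p_value=float(p),
        n_permutations=n_perm,
        per_locus=per_locus,
        excluded_populations=excluded,
    )


def pairwise_fst(
    g: GenotypeMatrix,
    pops: PopulationMap,
    n_perm: int = 10_000,
    seed: int = 0,
    distance: str = "allele",
    bonferroni_adjust: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """F_ST and permutation p for every population pair (two-pop AMOVAs).

    Returns ``(fst_matrix, p_matrix)`` as symmetric DataFrames with zero
    diagonals; with ``bonferroni_adjust`` the p-values are multiplied by the
    number of pairs (capped at 1).
    """
    names = pops.populations()
    labels = pops.labels_for(g)
    fst = pd.DataFrame(0.0, index=names, columns=names)
    pv = pd.DataFrame(np.nan, index=names, columns=names)
    np.fill_diagonal(pv.values, 0.0)
    pairs = list(combinations(range(len(names)), 2))
    rng = np.random.default_rng(seed)
    for i, j in pairs:
        idx = np.flatnonzero(np.isin(labels, [i, j]))
        sub = g.subset_individuals(idx)
        sub_map = PopulationMap({ind: pops.assignment[ind] for ind in sub.individuals})
        res = amova(
            sub, sub_map, n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)), distance=distance,
        )
        fst.iloc[i, j] = fst.iloc[j, i] = res.fst
        pv.iloc[i, j] = pv.iloc[j, i] = res.p_value
    if bonferroni_adjust:
        off = ~np.eye(len(names), dtype=bool)
        pv.values[off] = np.minimum(1.0, pv.values[off] * len(pairs))
    return fst, pv


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------

@dataclass
class DapcResult:
    n_pca: int
    k: int
    groups: np.ndarray              # group index per individual
    coordinates: np.ndarray | None  # discriminant-axis scores
    assignment_probabilities: np.ndarray | None
    bic: pd.Series | None           # BIC per candidate k (when groups inferred)
    no_structure: bool = False


def allele_dosage_matrix(g: GenotypeMatrix, scale: bool = False) -> tuple[np.ndarray, list[str]]:
    """Individuals x alleles matrix of dosages/ploidy, centred by column.

    Missing genotypes are replaced by the column mean before centring.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for j, meta in enumerate(g.loci):
        calls = g.calls[:, j, :]
        obs = np.unique(calls[calls != MISSING])
        for al in obs:
            dose = (calls == al).sum(axis=1) / 2.0
            dose = np.where(calls[:, 0] == MISSING, np.nan, dose)
            cols.append(dose)
            names.append(f"{meta.name}.{al}")
    X = np.column_stack(cols)
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mu, X) - mu
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = X / np.where(sd > 0, sd, 1.0)
    return X, names


def _cluster_bic(scores: np.ndarray, k: int, seed: int) -> tuple[float, np.ndarray]:
    """BIC of a k-component Gaussian mixture on PC scores, with its labels.

    Cluster centres are initialized from k-means; the full-covariance mixture
    likelihood gives a selection score conservative enough not to split a
    single panmictic cloud.
    """
    from sklearn.mixture import GaussianMixture

    n, d = scores.shape
    gm = GaussianMixture(
        n_components=k, covariance_type="full", n_init=3, random_state=seed,
        reg_covar=1e-4,
    ).fit(scores)
    return float(gm.bic(scores)), gm.predict(scores)


def dapc(
    g: GenotypeMatrix,
    n_pca: int | None = None,
    k: int | PopulationMap | None = None,
    k_max: int | None = None,
    seed: int = 0,
    scale: bool = False,
) -> DapcResult:
    """Discriminant analysis of principal components on allele dosages.

    With ``k`` a :class:`PopulationMap`, those labels are the groups (the
    "with priors" analysis); with ``k`` an int, a k-means-initialized
    Gaussian mixture on the retained PC scores builds the groups; with
    ``k=None`` the group number is chosen by the minimum mixture BIC over
    ``k = 1..k_max``. ``n_pca`` defaults to
    enough axes for 90 % of variance (capped below the sample size).
    """
    X, _ = allele_dosage_matrix(g, scale=scale)
    n = X.shape[0]
    max_pc = min(n - 1, X.shape[1])
    full = PCA(n_components=max_pc, random_state=seed).fit(X)
    if n_pca is None:
        cum = np.cumsum(full.explained_variance_ratio_)
        n_pca = int(np.searchsorted(cum, 0.9) + 1)
    n_pca = min(n_pca, max_pc)
    scores = full.transform(X)[:, :n_pca]

    bic_series = None
    if isinstance(k, PopulationMap):
        groups = k.labels_for(g)
    elif isinstance(k, int):
        _, groups = _cluster_bic(scores, k, seed)
    else:
        k_max = k_max if k_max is not None else min(n - 1, 10)
        bics, labelings = [], []
        for kk in range(1, k_max + 1):
            bic, lab = _cluster_bic(scores, kk, seed)
            bics.append(bic)
            labelings.append(lab)
        bic_series = pd.Series(bics, index=range(1, k_max + 1), name="BIC")
        best = int(bic_series.idxmin())
        groups = labelings[best - 1]
    k_eff = len(np.unique(groups))
    if k_eff < 2:
        return DapcResult(
            n_pca=n_pca, k=1, groups=np.zeros(n, dtype=int),
            coordinates=None, assignment_probabilities=None,
            bic=bic_series, no_structure=True,
        )
    lda = LinearDiscriminantAnalysis(n_components=min(k_eff - 1, n_pca))
    lda.fit(scores, groups)
    coords = lda.transform(scores)
    probs = lda.predict_proba(scores)
    return DapcResult(
        n_pca=n_pca, k=k_eff, groups=np.asarray(groups),
        coordinates=coords, assignment_probabilities=probs, bic=bic_series,
    )
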