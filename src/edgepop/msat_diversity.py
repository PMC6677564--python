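"""Per-locus and per-population microsatellite diversity statistics.

Implements the classic single-species battery: allele frequencies, number of
alleles (A), Nei's unbiased gene diversity (GD), rarefied allelic richness
(AR), polymorphic information content (PIC), observed/expected
heterozygosity, Weir & Cockerham's inbreeding coefficient F_IS with a
within-population allele-permutation test, null-allele frequency estimators
(Chakraborty; Brookfield-1), an exact Hardy–Weinberg test (full Levene
enumeration with a Monte-Carlo fallback), a genotypic linkage-disequilibrium
permutation test, Bonferroni correction and private-allele counts.

Conventions: gene diversity uses the unbiased n/(n-1) correction on gene
copies; the plug-in (uncorrected) expected heterozygosity is used inside the
PIC and null-allele formulas. Missing genotypes are excluded locus-wise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "AlleleFreqTable",
    "allele_frequencies",
    "gene_diversity",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "pic",
    "allelic_richness",
    "f_is",
    "null_allele_frequency",
    "hwe_exact_test",
    "bonferroni",
    "genotypic_ld_test",
    "private_alleles",
    "diversity_table",
]


@dataclass
class AlleleFreqTable:
    """Allele counts/frequencies per locus (one stratum)."""

    locus_names: list[str]
    counts: list[dict[int, int]]  # allele -> gene-copy count
    n_genes: np.ndarray  # non-missing gene copies per locus

    def frequencies(self, locus: int) -> dict[int, float]:
        n = self.n_genes[locus]
        if n == 0:
            return {}
        return {a: c / n for a, c in self.counts[locus].items()}

    def n_alleles(self) -> np.ndarray:
        return np.array([len(c) for c in self.counts])


def _locus_counts(calls: np.ndarray) -> dict[int, int]:
    obs = calls[calls != MISSING]
    vals, cnt = np.unique(obs, return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, cnt)}


def allele_frequencies(
    g: GenotypeMatrix, stratify: PopulationMap | None = None
) -> AlleleFreqTable | dict[str, AlleleFreqTable]:
    """Tally allele copies per locus, pooled or per population.

    Each non-missing gene copy counts once; loci where every call is missing
    get an empty count dict and ``n_genes = 0``.
    """
    if stratify is None:
        counts = [_locus_counts(g.calls[:, j, :]) for j in range(g.n_loci)]
        n_genes = np.array([sum(c.values()) for c in counts])
        return AlleleFreqTable(g.locus_names, counts, n_genes)
    labels = stratify.labels_for(g)
    out: dict[str, AlleleFreqTable] = {}
    for p, name in enumerate(stratify.populations()):
        sub = g.subset_individuals(np.flatnonzero(labels == p))
        out[name] = allele_frequencies(sub)
    return out


def gene_diversity(freqs: AlleleFreqTable) -> np.ndarray:
    """Nei's unbiased gene diversity per locus: GD = n(1 - sum p^2)/(n - 1)."""
    out = np.zeros(len(freqs.counts))
    for j, counts in enumerate(freqs.counts):
        n = freqs.n_genes[j]
        if n < 2:
            out[j] = np.nan
            continue
        p2 = sum((c / n) ** 2 for c in counts.values())
        out[j] = n * (1.0 - p2) / (n - 1.0)
    return out


def expected_heterozygosity(freqs: AlleleFreqTable, unbiased: bool = False) -> np.ndarray:
    """Plug-in He = 1 - sum p^2 per locus (or the unbiased variant)."""
    if unbiased:
        return gene_diversity(freqs)
    out = np.zeros(len(freqs.counts))
    for j, counts in enumerate(freqs.counts):
        n = freqs.n_genes[j]
        out[j] = 1.0 - sum((c / n) ** 2 for c in counts.values()) if n else np.nan
    return out


def observed_heterozygosity(g: GenotypeMatrix) -> np.ndarray:
    """Proportion of heterozygous genotypes per locus (missing excluded)."""
    out = np.zeros(g.n_loci)
    for j in range(g.n_loci):
        col = g.calls[:, j, :]
        ok = col[:, 0] != MISSING
        out[j] = np.mean(col[ok, 0] != col[ok, 1]) if ok.any() else np.nan
    return out


def pic(freqs: AlleleFreqTable) -> np.ndarray:
    """Polymorphic information content: 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    out = np.zeros(len(freqs.counts))
    for j in range(len(freqs.counts)):
        p = np.array(list(freqs.frequencies(j).values()))
        if p.size == 0:
            out[j] = np.nan
            continue
        p2 = p**2
        cross = (p2.sum() ** 2 - (p2**2).sum())  # 2 * sum_{i<j} p_i^2 p_j^2
        out[j] = 1.0 - p2.sum() - cross
    return out


def _rarefied_richness(counts: dict[int, int], g: int) -> float:
    n = sum(counts.values())
    if g > n:
        raise ValueError(f"rarefaction size {g} exceeds sample of {n} genes")
    total = 0.0
    lc_ng = gammaln(n + 1) - gammaln(g + 1) - gammaln(n - g + 1)
    for ni in counts.values():
        if n - ni < g:
            total += 1.0
            continue
        lc = gammaln(n - ni + 1) - gammaln(g + 1) - gammaln(n - ni - g + 1)
        total += 1.0 - np.exp(lc - lc_ng)
    return total


def allelic_richness(
    freqs: AlleleFreqTable | dict[str, AlleleFreqTable], g: int | None = None
) -> np.ndarray | pd.DataFrame:
    """Rarefied allelic richness AR(g) = sum_i [1 - C(N-N_i, g)/C(N, g)].

    ``g`` is the standardized number of gene copies; by default the smallest
    per-stratum non-missing gene count across loci. With a dict of per-
    population tables, returns a loci x populations DataFrame rarefied to the
    common minimum.
    """
    if isinstance(freqs, dict):
        if g is None:
            g = int(min(t.n_genes.min() for t in freqs.values()))
        data = {
            pop: [_rarefied_richness(c, g) for c in t.counts]
            for pop, t in freqs.items()
        }
        first = next(iter(freqs.values()))
        return pd.DataFrame(data, index=first.locus_names)
    if g is None:
        g = int(freqs.n_genes.min())
    return np.array([_rarefied_richness(c, g) for c in freqs.counts])


# ---------------------------------------------------------------------------
# F_IS (Weir & Cockerham variance components)
# ---------------------------------------------------------------------------

def _wc_components(calls: np.ndarray, labels: np.ndarray):
    """Per-allele (a, b, c) Weir–Cockerham components at one locus.

    ``calls`` is (n_ind, 2); returns summed b and c (and a) over alleles.
    F_IS uses only b and c, so the formula stays defined for one population
    (the among-population terms vanish).
    """
    ok = calls[:, 0] != MISSING
    calls, labels = calls[ok], labels[ok]
    pops = np.unique(labels)
    ni = np.array([(labels == p).sum() for p in pops], dtype=float)
    keep = ni > 0
    pops, ni = pops[keep], ni[keep]
    r = len(pops)
    if r == 0 or calls.size == 0:
        return 0.0, 0.0, 0.0
    alleles = np.unique(calls)
    nbar = ni.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (ni**2).sum() / (r * nbar)) / (r - 1) if r > 1 else np.nan
    A = B = C = 0.0
    het = calls[:, 0] != calls[:, 1]
    for al in alleles:
        dose = (calls == al).sum(axis=1) / 2.0  # 0, .5, 1
        p_i = np.array([dose[labels == p].mean() for p in pops])
        h_ind = het & (calls == al).any(axis=1)
        h_i = np.array([h_ind[labels == p].mean() for p in pops])
        pbar = (ni * p_i).sum() / (r * nbar)
        hbar = (ni * h_i).sum() / (r * nbar)
        if r > 1:
            s2 = (ni * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        else:
            s2 = 0.0
        frac = (r - 1) / r if r > 1 else 0.0
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - frac * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        if r > 1:
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - frac * s2 - hbar / 4.0) / (nbar - 1)
            )
        else:
            a = 0.0
        A += a
        B += b
        C += c
    return A, B, C


def _fis_from_components(bc: list[tuple[float, float]]) -> float:
    b = sum(x[0] for x in bc)
    c = sum(x[1] for x in bc)
    denom = b + c
    return 1.0 - c / denom if denom > 0 else np.nan


def f_is(
    g: GenotypeMatrix,
    pops: PopulationMap | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Weir & Cockerham F_IS per locus and overall, with permutation p-values.

    The null randomizes alleles among individuals *within* populations
    (re-pairing the observed gene copies), which destroys departures from
    Hardy–Weinberg while preserving allele frequencies. Two-sided p with the
    (k+1)/(B+1) estimator. With ``pops=None`` all individuals form one unit.
    """
    if pops is None:
        labels = np.zeros(g.n_individuals, dtype=int)
    else:
        labels = pops.labels_for(g)
    rng = np.random.default_rng(seed)

    per_locus = [_wc_components(g.calls[:, j, :], labels) for j in range(g.n_loci)]
    obs = np.array([_fis_from_components([(b, c)]) for _, b, c in per_locus])
    overall = _fis_from_components([(b, c) for _, b, c in per_locus])

    ge = np.zeros(g.n_loci + 1)
    le = np.zeros(g.n_loci + 1)
    valid = 0
    for _ in range(n_perm):
        perm = _permute_within(g.calls, labels, rng)
        comp = [_wc_components(perm[:, j, :], labels) for j in range(g.n_loci)]
        vals = np.array([_fis_from_components([(b, c)]) for _, b, c in comp])
        tot = _fis_from_components([(b, c) for _, b, c in comp])
        allv = np.append(vals, tot)
        obs_all = np.append(obs, overall)
        ge += allv >= obs_all - 1e-12
        le += allv <= obs_all + 1e-12
        valid += 1
    p = np.minimum(1.0, 2 * np.minimum(ge + 1, le + 1) / (valid + 1))
    est = np.append(obs, overall)
    return pd.DataFrame(
        {"fis": est, "p_value": p},
        index=g.locus_names + ["overall"],
    )


def _permute_within(calls: np.ndarray, labels: np.ndarray, rng) -> np.ndarray:
    """Re-pair gene copies at random within each population, per locus."""
    out = calls.copy()
    for p in np.unique(labels):
        rows = np.flatnonzero(labels == p)
        for j in range(calls.shape[1]):
            block = out[rows, j, :]
            ok = block[:, 0] != MISSING
            genes = block[ok].ravel()
            rng.shuffle(genes)
            block[ok] = genes.reshape(-1, 2)
            out[rows, j, :] = block
    return out


# ---------------------------------------------------------------------------
# null alleles
# ---------------------------------------------------------------------------

def null_allele_frequency(g: GenotypeMatrix) -> pd.DataFrame:
    """Chakraborty and Brookfield-1 null-allele estimates per locus.

    Chakraborty: r = (He - Ho)/(He + Ho); Brookfield-1: r = (He - Ho)/(1 + He),
    with plug-in He. Negative values (heterozygote excess) are reported as-is.
    """
    freqs = allele_frequencies(g)
    he = expected_heterozygosity(freqs)
    ho = observed_heterozygosity(g)
    with np.errstate(divide="ignore", invalid="ignore"):
        chak = np.where(he + ho > 0, (he - ho) / (he + ho), np.nan)
    brook = (he - ho) / (1.0 + he)
    return pd.DataFrame(
        {"chakraborty": chak, "brookfield1": brook}, index=g.locus_names
    )


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

def _log_table_weight(geno_counts: dict[tuple[int, int], int]) -> float:
    """Table-dependent part of the Levene log-probability: h log2 - sum log n_ij!."""
    h = sum(c for (a, b), c in geno_counts.items() if a != b)
    return h * np.log(2.0) - sum(gammaln(c + 1) for c in geno_counts.values())


def _enumerate_tables(allele_counts: np.ndarray, cap: int):
    """Yield genotype tables (upper-tri count dicts) with the given allele margins.

    Stops (returns None) when more than ``cap`` tables would be generated.
    """
    k = len(allele_counts)
    pairs = [(i, j) for i in range(k) for j in range(i, k)]
    tables: list[dict[tuple[int, int], int]] = []

    def rec(idx: int, remaining: np.ndarray, current: dict):
        if len(tables) > cap:
            return False
        if idx == len(pairs):
            if remaining.sum() == 0:
                tables.append(dict(current))
            return True
        i, j = pairs[idx]
        # entering row i: every earlier allele's copies must be fully placed
        if j == i and i > 0 and remaining[i - 1] != 0:
            return True
        if i == j:
            later = remaining[i + 1:].sum() if i + 1 <= k else 0
            # remaining copies of allele i must all be placed in cells (i, j>=i)
            max_c = remaining[i] // 2
            for c in range(max_c + 1):
                rest_i = remaining[i] - 2 * c
                # copies of i left must be pairable with later alleles
                if rest_i > later:
                    continue
                remaining[i] -= 2 * c
                current[(i, j)] = c
                if not rec(idx + 1, remaining, current):
                    return False
                remaining[i] += 2 * c
            current.pop((i, j), None)
            return True
        max_c = min(remaining[i], remaining[j])
        for c in range(max_c + 1):
            remaining[i] -= c
            remaining[j] -= c
            current[(i, j)] = c
            if not rec(idx + 1, remaining, current):
                return False
            remaining[i] += c
            remaining[j] += c
        current.pop((i, j), None)
        return True

    ok = rec(0, allele_counts.copy(), {})
    return tables if ok and len(tables) <= cap else None


def hwe_exact_test(
    g: GenotypeMatrix,
    locus: int | str,
    pops: PopulationMap | None = None,
    n_mc: int = 100_000,
    enum_cap: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Exact Hardy–Weinberg test for one locus, pooled or per population.

    The null is Levene's conditional distribution of genotype tables given
    allele counts. When the table space has at most ``enum_cap`` tables the
    p-value is exact (sum of probabilities <= the observed table's); larger
    spaces use Monte-Carlo sampling by random re-pairing of the observed gene
    copies, which draws i.i.d. from the same null. Monomorphic loci return
    p = 1 flagged ``not testable``. The sign of F_IS gives the direction of
    any departure (deficit vs excess of heterozygotes).
    """
    j = locus if isinstance(locus, int) else g.locus_names.index(locus)
    strata: list[tuple[str, np.ndarray]] = []
    if pops is None:
        strata.append(("all", g.calls[:, j, :]))
    else:
        labels = pops.labels_for(g)
        for p, name in enumerate(pops.populations()):
            strata.append((name, g.calls[labels == p, j, :]))
    rows = []
    rng = np.random.default_rng(seed)
    for name, calls in strata:
        obs_calls = calls[calls[:, 0] != MISSING]
        alleles, counts = np.unique(obs_calls, return_counts=True)
        if len(alleles) < 2 or len(obs_calls) < 3:
            rows.append({"stratum": name, "p_value": 1.0, "method": "not testable"})
            continue
        amap = {int(a): i for i, a in enumerate(alleles)}
        geno: dict[tuple[int, int], int] = {}
        for a, b in obs_calls:
            key = tuple(sorted((amap[int(a)], amap[int(b)])))
            geno[key] = geno.get(key, 0) + 1
        obs_w = _log_table_weight(geno)
        tables = _enumerate_tables(counts.astype(np.int64), enum_cap)
        if tables is not None:
            ws = np.array([_log_table_weight(t) for t in tables])
            probs = np.exp(ws - ws.max())
            probs /= probs.sum()
            obs_p = np.exp(obs_w - ws.max()) / np.exp(ws - ws.max()).sum()
            p = probs[probs <= obs_p * (1 + 1e-9)].sum()
            rows.append({"stratum": name, "p_value": float(p), "method": "enumeration"})
        else:
            genes = obs_calls.ravel().copy()
            hits = 0
            for _ in range(n_mc):
                rng.shuffle(genes)
                sim: dict[tuple[int, int], int] = {}
                it = genes.reshape(-1, 2)
                for a, b in it:
                    key = tuple(sorted((amap[int(a)], amap[int(b)])))
                    sim[key] = sim.get(key, 0) + 1
                if _log_table_weight(sim) <= obs_w + 1e-12:
                    hits += 1
            rows.append(
                {
                    "stratum": name,
                    "p_value": (hits + 1) / (n_mc + 1),
                    "method": "monte-carlo",
                }
            )
    return pd.DataFrame(rows).set_index("stratum")


def bonferroni(pvals, nominal: float = 0.05) -> np.ndarray:
    """Significance calls under Bonferroni: p < nominal/m for m simultaneous tests."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    return p < nominal / p.size


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def _geno_codes(calls: np.ndarray) -> np.ndarray:
    """Unordered-genotype integer code per individual (missing -> -1)."""
    lo = np.minimum(calls[:, 0], calls[:, 1])
    hi = np.maximum(calls[:, 0], calls[:, 1])
    codes = lo * 10_000 + hi
    codes[calls[:, 0] == MISSING] = -1
    return codes


def _g_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Log-likelihood-ratio statistic of the two-locus genotype table."""
    ok = (x >= 0) & (y >= 0)
    x, y = x[ok], y[ok]
    if x.size == 0:
        return 0.0
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    table = np.zeros((len(xv), len(yv)))
    np.add.at(table, (xi, yi), 1)
    n = table.sum()
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / exp), 0.0)
    return 2.0 * terms.sum()


def genotypic_ld_test(
    g: GenotypeMatrix,
    pops: PopulationMap | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise-locus genotypic association test.

    For each pair of polymorphic loci, the G (log-likelihood-ratio) statistic
    of the two-locus genotype contingency table is summed over populations;
    the null permutes one locus's genotypes among individuals within
    populations. Returns an empty frame with fewer than two polymorphic loci.
    """
    poly = np.flatnonzero(g.is_polymorphic())
    if len(poly) < 2:
        return pd.DataFrame(columns=["locus1", "locus2", "p_value"])
    labels = (
        np.zeros(g.n_individuals, dtype=int) if pops is None else pops.labels_for(g)
    )
    rng = np.random.default_rng(seed)
    codes = {j: _geno_codes(g.calls[:, j, :]) for j in poly}
    groups = [np.flatnonzero(labels == p) for p in np.unique(labels)]
    rows = []
    for j1, j2 in combinations(poly, 2):
        x, y = codes[j1], codes[j2]
        obs = sum(_g_statistic(x[rows_], y[rows_]) for rows_ in groups)
        hits = 0
        for _ in range(n_perm):
            yp = y.copy()
            for rows_ in groups:
                yp[rows_] = yp[rng.permutation(rows_)]
            stat = sum(_g_statistic(x[rows_], yp[rows_]) for rows_ in groups)
            if stat >= obs - 1e-12:
                hits += 1
        rows.append(
            {
                "locus1": g.locus_names[j1],
                "locus2": g.locus_names[j2],
                "p_value": (hits + 1) / (n_perm + 1),
            }
        )
    return pd.DataFrame(rows)


def private_alleles(g: GenotypeMatrix, pops: PopulationMap) -> pd.Series:
    """Number of alleles observed in exactly one population (E), per population."""
    tables = allele_frequencies(g, stratify=pops)
    names = list(tables)
    if len(names) < 2:
        raise ValueError("private alleles need at least two populations")
    counts = pd.Series(0, index=names, dtype=int)
    for j in range(g.n_loci):
        presence = {p: set(tables[p].counts[j]) for p in names}
        for p in names:
            others = set().union(*(presence[q] for q in names if q != p))
            counts[p] += len(presence[p] - others)
    return counts


# ---------------------------------------------------------------------------
# combined table
# ---------------------------------------------------------------------------

def diversity_table(
    g: GenotypeMatrix,
    pops: PopulationMap | None = None,
    rarefaction_g: int | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-locus summary mirroring the standard A/PIC/GD/AR/Ho/He/F_IS/NUL layout."""
    freqs = allele_frequencies(g)
    table = pd.DataFrame(index=g.locus_names)
    table["A"] = freqs.n_alleles()
    table["PIC"] = pic(freqs)
    table["GD"] = gene_diversity(freqs)
    if pops is not None:
        strat = allele_frequencies(g, stratify=pops)
        ar = allelic_richness(strat, g=rarefaction_g)
        table["AR"] = ar.mean(axis=1).values
    else:
        table["AR"] = allelic_richness(freqs, g=rarefaction_g)
    table["Ho"] = observed_heterozygosity(g)
    table["He"] = expected_heterozygosity(freqs)
    fis = f_is(g, pops, n_perm=n_perm, seed=seed)
    table["Fis"] = fis["fis"].values[:-1]
    table["Fis_p"] = fis["p_value"].values[:-1]
    nul = null_allele_frequency(g)
    table["NUL"] = nul["brookfield1"].values
    return table
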