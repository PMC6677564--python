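"""Study-shaped synthetic datasets with known ground truth.

Two generator profiles emulate the sampling designs of the two range-edge
endemics analysed by the pipeline:

* ``mantiqueirensis-like`` — 7 small sites totalling 38 individuals, 12
  microsatellite loci of which exactly 10 are polymorphic, weak population
  structure (target F_ST around 0.05–0.1), random mating (no inbreeding) and
  a single plastid haplotype over two concatenated spacer regions
  (471 + 650 bp).
* ``elegans-like`` — 4 sites totalling 81 individuals, 5 polymorphic of 14
  loci, partial selfing (equilibrium F_IS = s/(2 - s)), one strongly
  diverged site, and two plastid haplotypes at 79:2 over 445 + 746 bp.

Population allele frequencies follow the Balding–Nichols model: site
frequencies are Dirichlet-distributed around ancestral frequencies with
concentration (1 - F)/F, so the differentiation parameter F is the expected
F_ST and is recorded in the ground-truth sidecar. Selfing is imposed at the
genotype-pairing stage: with probability s/(2 - s) an individual's two gene
copies are identical by descent, which yields the classical equilibrium
inbreeding coefficient exactly. Single-population demographic truths for
ABC experiments come from the coalescent GSM simulator.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coalescent_gsm import MutationModel, ScenarioSpec, simulate_dataset
from .datatypes import AlignmentSet, GenotypeMatrix, LocusMeta, PopulationMap

_BASE_PROBS = {"A": 0.36, "C": 0.14, "G": 0.15, "T": 0.35}  # ~29 % GC


@dataclass
class SyntheticDataset:
    """A generated dataset bundled with the truth that produced it."""

    genotypes: GenotypeMatrix
    popmap: PopulationMap
    regions: list[AlignmentSet]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        from .io_formats import write_fasta, write_genotypes

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genotypes(self.genotypes, self.popmap, outdir / "genotypes.gen")
        write_genotypes(self.genotypes, self.popmap, outdir / "genotypes.csv", "csv")
        for reg in self.regions:
            write_fasta(reg, outdir / f"{reg.region}.fasta")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2))


def _balding_nichols_freqs(
    ancestral: np.ndarray, F: float, rng: np.random.Generator
) -> np.ndarray:
    if F <= 0:
        return ancestral
    return rng.dirichlet(ancestral * (1.0 - F) / F)


def _sample_genotypes(
    pop_freqs: np.ndarray, alleles: np.ndarray, n: int, s_ibd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n, 2) diploid calls; with probability ``s_ibd`` the copies are IBD."""
    out = np.empty((n, 2), dtype=np.int64)
    for i in range(n):
        if rng.random() < s_ibd:
            a = rng.choice(alleles, p=pop_freqs)
            out[i] = (a, a)
        else:
            out[i] = rng.choice(alleles, p=pop_freqs, size=2)
    return out


def _make_locus(
    name: str, n_alleles: int, rng: np.random.Generator, motif: int = 2
) -> tuple[LocusMeta, np.ndarray, np.ndarray]:
    """Locus metadata plus allele values and ancestral frequencies."""
    start = int(rng.integers(8, 20))
    values = start + np.arange(n_alleles)
    meta = LocusMeta(name, motif, (int(values[0] - 3), int(values[-1] + 3)))
    freqs = rng.dirichlet(np.full(n_alleles, 1.5))
    return meta, values, freqs


def _structured_genotypes(
    pop_sizes: list[int],
    locus_alleles: list[int],
    monomorphic: int,
    F_per_pop: list[float],
    selfing: float,
    rng: np.random.Generator,
    pop_prefix: str,
):
    """Genotype matrix + popmap under Balding–Nichols structure with selfing.

    Loci observed monomorphic in the sample are redrawn so the polymorphic
    count is exact by construction.
    """
    n_pops = len(pop_sizes)
    s_ibd = selfing / (2.0 - selfing) if selfing > 0 else 0.0
    names = [f"{pop_prefix}{i + 1}" for i in range(n_pops)]
    inds: list[str] = []
    pop_of: dict[str, str] = {}
    for p, (name, size) in enumerate(zip(names, pop_sizes)):
        for i in range(size):
            ind = f"{name}_{i + 1}"
            inds.append(ind)
            pop_of[ind] = name
    n_ind = len(inds)
    starts = np.cumsum([0] + pop_sizes)

    loci: list[LocusMeta] = []
    columns: list[np.ndarray] = []
    for j, k in enumerate(locus_alleles):
        locus_name = f"L{j + 1:02d}"
        for _attempt in range(200):
            meta, values, anc = _make_locus(locus_name, k, rng)
            col = np.empty((n_ind, 2), dtype=np.int64)
            for p in range(n_pops):
                pf = _balding_nichols_freqs(anc, F_per_pop[p], rng)
                block = _sample_genotypes(
                    pf, values, pop_sizes[p], s_ibd, rng
                )
                col[starts[p] : starts[p + 1]] = block
            if np.unique(col).size >= 2:
                break
        else:  # pragma: no cover - p(monomorphic)^200 is negligible
            raise RuntimeError("could not generate a polymorphic locus")
        loci.append(meta)
        columns.append(col)
    for j in range(monomorphic):
        locus_name = f"M{j + 1:02d}"
        value = int(rng.integers(10, 18))
        meta = LocusMeta(locus_name, 2, (value - 3, value + 3))
        loci.append(meta)
        columns.append(np.full((n_ind, 2), value, dtype=np.int64))

    calls = np.stack(columns, axis=1)
    g = GenotypeMatrix(inds, loci, calls)
    return g, PopulationMap(pop_of), names


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    bases = list(_BASE_PROBS)
    probs = np.array(list(_BASE_PROBS.values()))
    return "".join(rng.choice(bases, p=probs, size=length))


def _plastid_regions(
    ids: list[str],
    lengths: tuple[int, int],
    hap_assignment: list[int],
    rng: np.random.Generator,
    region_names: tuple[str, str] = ("trnH-psbA", "trnS-trnG"),
) -> list[AlignmentSet]:
    """Two aligned regions; haplotype 1 differs from 0 at one site in region 2."""
    base = [_random_sequence(L, rng) for L in lengths]
    variant = list(base[1])
    pos = int(rng.integers(0, lengths[1]))
    old = variant[pos]
    variant[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[old]
    variant = "".join(variant)
    regions = []
    for r, name in enumerate(region_names):
        seqs = []
        for h in hap_assignment:
            if r == 1 and h == 1:
                seqs.append(variant)
            else:
                seqs.append(base[r])
        regions.append(AlignmentSet(ids=list(ids), sequences=seqs, region=name))
    return regions


def generate_mantiqueirensis_like(seed: int) -> SyntheticDataset:
    """7 sites / 38 individuals / 12 loci (10 polymorphic), weak structure."""
    rng = np.random.default_rng(seed)
    pop_sizes = [8, 6, 7, 4, 5, 4, 4]  # sums to 38
    locus_alleles = [int(k) for k in rng.integers(2, 8, size=10)]
    F = 0.08
    g, pm, names = _structured_genotypes(
        pop_sizes, locus_alleles, monomorphic=2,
        F_per_pop=[F] * len(pop_sizes), selfing=0.0,
        rng=rng, pop_prefix="Mant",
    )
    regions = _plastid_regions(
        g.individuals, (471, 650), [0] * g.n_individuals, rng
    )
    truth = {
        "profile": "mantiqueirensis-like",
        "seed": seed,
        "pop_sizes": pop_sizes,
        "F_per_pop": [F] * len(pop_sizes),
        "target_fst_band": [0.03, 0.15],
        "selfing": 0.0,
        "expected_fis": 0.0,
        "n_polymorphic": 10,
        "plastid_haplotypes": 1,
    }
    return SyntheticDataset(g, pm, regions, truth)


def generate_elegans_like(seed: int, selfing: float = 0.58) -> SyntheticDataset:
    """4 sites / 81 individuals / 14 loci (5 polymorphic), selfing, one diverged site."""
    rng = np.random.default_rng(seed)
    pop_sizes = [30, 10, 21, 20]  # sums to 81; site 2 is small and diverged
    locus_alleles = [int(k) for k in rng.integers(4, 14, size=5)]
    F_per_pop = [0.06, 0.65, 0.06, 0.06]
    g, pm, names = _structured_genotypes(
        pop_sizes, locus_alleles, monomorphic=9,
        F_per_pop=F_per_pop, selfing=selfing,
        rng=rng, pop_prefix="Eleg",
    )
    hap = [0] * g.n_individuals
    rare = rng.choice(pop_sizes[0], size=2, replace=False)  # rare hap only in site 1
    for i in rare:
        hap[int(i)] = 1
    regions = _plastid_regions(g.individuals, (445, 746), hap, rng)
    truth = {
        "profile": "elegans-like",
        "seed": seed,
        "pop_sizes": pop_sizes,
        "F_per_pop": F_per_pop,
        "diverged_pop": "Eleg2",
        "selfing": selfing,
        "expected_fis": selfing / (2.0 - selfing),
        "n_polymorphic": 5,
        "plastid_haplotypes": 2,
        "plastid_hap_counts": [79, 2],
    }
    return SyntheticDataset(g, pm, regions, truth)


def generate_bottleneck_truth(
    scenario_id: int,
    params: dict[str, float],
    panel: list[LocusMeta],
    n_ind: int,
    seed: int,
    mutation: MutationModel | None = None,
) -> tuple[GenotypeMatrix, dict]:
    """Single-population dataset simulated under a known demographic truth.

    Returns the genotype matrix and a sidecar dict recording the scenario,
    parameters and seed, sufficient to score scenario-choice and
    parameter-recovery experiments.
    """
    rng = np.random.default_rng(seed)
    spec = ScenarioSpec(scenario_id)
    g = simulate_dataset(spec, params, panel, n_ind, rng, mutation)
    truth = {
        "scenario_id": scenario_id,
        "params": dict(params),
        "n_ind": n_ind,
        "seed": seed,
        "loci": [m.name for m in panel],
    }
    return g, truth


def study_panel(species: str) -> tuple[list[LocusMeta], int]:
    """Locus panel shaped like one species' polymorphic markers: (panel, n_ind).

    ``"mant"``: 10 dinucleotide loci, 38 individuals; ``"eleg"``: 5 loci,
    81 individuals. Allele ranges are 30 repeat units wide, wide enough for
    the mutational priors to explore.
    """
    if species == "mant":
        n_loci, n_ind = 10, 38
    elif species == "eleg":
        n_loci, n_ind = 5, 81
    else:
        raise ValueError("species must be 'mant' or 'eleg'")
    panel = [
        LocusMeta(f"SSR{j + 1:02d}", 2, (5, 35)) for j in range(n_loci)
    ]
    return panel, n_ind
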