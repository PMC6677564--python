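"""Shared data model: locus metadata, genotype matrices, population maps, alignments.

Allele calls are stored internally as integer repeat counts. Missing calls use
the sentinel :data:`MISSING` (-1); a genotype is either fully observed (both
gene copies) or fully missing — half-calls are rejected at ingest.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Sentinel for a missing allele call (both copies of a genotype share it).
MISSING: int = -1


@dataclass(frozen=True)
class LocusMeta:
    """Metadata for one microsatellite locus.

    Parameters
    ----------
    name
        Unique locus identifier within a panel.
    motif_length
        Repeat-unit length in base pairs (>= 1).
    allele_range
        Inclusive (min, max) allele size in repeat units.
    ploidy
        Fixed at 2 (diploid).
    """

    name: str
    motif_length: int = 2
    allele_range: tuple[int, int] = (5, 50)
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError(f"locus {self.name}: motif_length must be >= 1")
        lo, hi = self.allele_range
        if not lo < hi:
            raise ValueError(f"locus {self.name}: allele_range min must be < max")
        if lo < 0:
            raise ValueError(
                f"locus {self.name}: allele sizes are repeat counts (>= 0)"
            )
        if self.ploidy != 2:
            raise ValueError("only diploid data are supported")


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls for ``individuals`` x ``loci``.

    ``calls`` has shape (n_individuals, n_loci, 2) and holds allele sizes in
    repeat units; missing genotypes are ``(MISSING, MISSING)``. The order of
    the two copies within a genotype carries no information.
    """

    individuals: list[str]
    loci: list[LocusMeta]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n_ind, n_loc = len(self.individuals), len(self.loci)
        if n_ind < 1 or n_loc < 1:
            raise ValueError("need at least one individual and one locus")
        if self.calls.shape != (n_ind, n_loc, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n_ind}, {n_loc}, 2)"
            )
        if len(set(self.individuals)) != n_ind:
            raise ValueError("individual ids must be unique")
        names = [m.name for m in self.loci]
        if len(set(names)) != n_loc:
            raise ValueError("locus names must be unique")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            raise ValueError("half-missing genotypes are not allowed")
        for j, meta in enumerate(self.loci):
            col = self.calls[:, j, :]
            obs = col[col != MISSING]
            lo, hi = meta.allele_range
            if obs.size and (obs.min() < lo or obs.max() > hi):
                raise ValueError(
                    f"locus {meta.name}: allele outside range [{lo}, {hi}]"
                )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [m.name for m in self.loci]

    def locus_calls(self, locus: int | str) -> np.ndarray:
        """(n_individuals, 2) calls at one locus (by index or name)."""
        j = locus if isinstance(locus, int) else self.locus_names.index(locus)
        return self.calls[:, j, :]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci), True where the genotype is missing."""
        return self.calls[:, :, 0] == MISSING

    def is_polymorphic(self) -> np.ndarray:
        """Boolean per locus: more than one distinct observed allele."""
        out = np.zeros(self.n_loci, dtype=bool)
        for j in range(self.n_loci):
            col = self.calls[:, j, :]
            out[j] = np.unique(col[col != MISSING]).size > 1
        return out

    def subset_individuals(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            [self.individuals[i] for i in keep], list(self.loci), self.calls[keep]
        )

    def subset_loci(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(
            list(self.individuals), [self.loci[j] for j in keep],
            self.calls[:, keep, :],
        )


@dataclass
class PopulationMap:
    """Assignment of individuals to population (site) labels.

    ``coordinates`` optionally stores decimal-degree (lat, lon) per site.
    """

    assignment: dict[str, str]
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)

    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.assignment.values():
            seen.setdefault(p, None)
        return list(seen)

    def labels_for(self, g: GenotypeMatrix) -> np.ndarray:
        """Integer population index per individual of ``g`` (first-appearance order)."""
        pops = self.populations()
        index = {p: i for i, p in enumerate(pops)}
        try:
            return np.array([index[self.assignment[ind]] for ind in g.individuals])
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"individual {exc} missing from population map") from exc

    def members(self, pop: str) -> list[str]:
        return [i for i, p in self.assignment.items() if p == pop]


@dataclass
class AlignmentSet:
    """Equal-length aligned nucleotide sequences over {A, C, G, T, -, N}."""

    ids: list[str]
    sequences: list[str]
    region: str = "region"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dup}")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment in region {self.region}: lengths {sorted(lengths)}")
        alphabet = set("ACGT-N")
        for i, s in zip(self.ids, self.sequences):
            bad = set(s) - alphabet
            if bad:
                raise ValueError(f"sequence {i}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def to_matrix(self) -> np.ndarray:
        """(n, L) array of single-character bytes."""
        return np.array([list(s) for s in self.sequences], dtype="U1")
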