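"""Haplotype identification and diversity for concatenated plastid alignments.

Haplotypes are equivalence classes of sequences identical at every retained
site. By default, alignment columns containing a gap or N are excluded
completely before comparison; ``site_exclusion="pairwise"`` instead ignores
such characters pair by pair when counting differences.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import AlignmentSet

_BASES = ("A", "C", "G", "T")


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with counts, plus variable-site bookkeeping."""

    haplotype_ids: list[str]
    haplotypes: list[str]          # sequences restricted to retained sites
    counts: np.ndarray
    assignment: list[str]          # haplotype id per input sequence
    variable_sites: dict[int, list[str]]  # original column -> observed states
    parsimony_informative: int
    n_excluded_sites: int

    @property
    def n_sequences(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def _retained_columns(mat: np.ndarray) -> np.ndarray:
    """Columns free of gaps and ambiguous bases (complete deletion)."""
    bad = (mat == "-") | (mat == "N")
    return ~bad.any(axis=0)


def identify_haplotypes(a: AlignmentSet, id_prefix: str = "H") -> HaplotypeTable:
    """Collapse an alignment into haplotypes and tally variable sites.

    Ids are assigned in decreasing-frequency order (ties broken by sequence,
    lexicographically). Variable sites are reported in original alignment
    coordinates; a site is parsimony-informative when at least two states
    each occur in at least two sequences.
    """
    if a.n_sequences == 0:
        raise ValueError("empty alignment")
    mat = a.to_matrix()
    keep = _retained_columns(mat)
    core = mat[:, keep]
    seqs = ["".join(row) for row in core]

    counts: dict[str, int] = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ids = [f"{id_prefix}{i + 1}" for i in range(len(ordered))]
    lookup = {s: h for h, (s, _) in zip(ids, ordered)}

    variable: dict[int, list[str]] = {}
    informative = 0
    orig_cols = np.flatnonzero(keep)
    for col, orig in zip(core.T, orig_cols):
        states, state_counts = np.unique(col, return_counts=True)
        if len(states) > 1:
            variable[int(orig)] = [str(s) for s in states]
            if (state_counts >= 2).sum() >= 2:
                informative += 1
    return HaplotypeTable(
        haplotype_ids=ids,
        haplotypes=[s for s, _ in ordered],
        counts=np.array([c for _, c in ordered]),
        assignment=[lookup[s] for s in seqs],
        variable_sites=variable,
        parsimony_informative=informative,
        n_excluded_sites=int((~keep).sum()),
    )


def haplotype_diversity(counts) -> tuple[float, float]:
    """Unbiased haplotype diversity h = n(1 - sum p_i^2)/(n - 1) and its s.d.

    The sampling variance is Nei's (1987) formula
    V(h) = 2/(n(n-1)) {2(n-2)[sum p^3 - (sum p^2)^2] + sum p^2 - (sum p^2)^2}.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype diversity needs at least two sequences")
    p = counts / n
    s2, s3 = (p**2).sum(), (p**3).sum()
    h = n * (1.0 - s2) / (n - 1.0)
    var = 2.0 / (n * (n - 1.0)) * (2.0 * (n - 2.0) * (s3 - s2**2) + s2 - s2**2)
    return float(h), float(np.sqrt(max(var, 0.0)))


def nucleotide_diversity(
    a: AlignmentSet, site_exclusion: str = "complete"
) -> tuple[float, float]:
    """Average pairwise per-site difference (pi) and its sampling s.d.

    With complete deletion, gap/N columns are removed before comparison; with
    pairwise deletion each pair is compared over its own unambiguous sites.
    The variance is the standard coalescent sampling formula
    V(pi) = (n+1) pi / (3(n-1) L) + 2 (n^2 + n + 3) pi^2 / (9 n (n-1)).
    """
    n = a.n_sequences
    if n < 2:
        raise ValueError("nucleotide diversity needs at least two sequences")
    mat = a.to_matrix()
    if site_exclusion == "complete":
        mat = mat[:, _retained_columns(mat)]
        L = mat.shape[1]
        if L == 0:
            raise ValueError("no sites left after gap/N exclusion")
        total = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                total += (mat[i] != mat[j]).sum() / L
        pi = total / (n * (n - 1) / 2)
    elif site_exclusion == "pairwise":
        good = np.isin(mat, _BASES)
        total = 0.0
        L_eff = []
        for i in range(n):
            for j in range(i + 1, n):
                ok = good[i] & good[j]
                if not ok.any():
                    continue
                total += (mat[i, ok] != mat[j, ok]).sum() / ok.sum()
                L_eff.append(ok.sum())
        pi = total / (n * (n - 1) / 2)
        L = int(np.mean(L_eff)) if L_eff else 0
    else:
        raise ValueError(f"unknown site_exclusion {site_exclusion!r}")
    if L == 0:
        raise ValueError("no comparable sites")
    var = (n + 1) * pi / (3.0 * (n - 1) * L) + (
        2.0 * (n**2 + n + 3) * pi**2 / (9.0 * n * (n - 1))
    )
    return float(pi), float(np.sqrt(max(var, 0.0)))


def gc_content(a: AlignmentSet) -> float:
    """(G + C) / (A + C + G + T) over the whole alignment; gaps and N excluded."""
    mat = a.to_matrix()
    base = np.isin(mat, _BASES).sum()
    if base == 0:
        raise ValueError("no unambiguous bases in alignment")
    gc = ((mat == "G") | (mat == "C")).sum()
    return float(gc / base)
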