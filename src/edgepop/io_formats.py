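"""Readers and writers for GenePop, genotype CSV and aligned FASTA.

Two genotype dialects are supported:

* ``genepop`` — classic GenePop text: a title line, one locus name per line
  (or a comma-separated list), then ``pop`` blocks of ``id , 0101 0102 ...``
  records. 2- vs 3-digit allele coding is auto-detected; allele 0 is missing.
* ``csv`` — a header row ``individual,population,<locus>_1,<locus>_2,...``
  with one column per allele copy and ``NA`` for missing calls.

Allele calls may be given either directly in repeat units or as fragment
sizes in base pairs (``units="bp"``); bp input is converted to repeat units
per locus using the motif length and an offset estimated as
``min observed size mod motif_length`` (flanking sequence), so the
conversion is a bijection given the locus metadata. Rounding applied to
off-ladder bp calls is recorded in the returned report.
"""
from __future__ import annotations

import csv as _csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import MISSING, AlignmentSet, GenotypeMatrix, LocusMeta, PopulationMap


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass
class IngestReport:
    """Bookkeeping from a genotype read: unit conversion and rounding events."""

    units: str = "repeat"
    offsets: dict[str, int] = field(default_factory=dict)
    rounded: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------

def _infer_locus_meta(name: str, alleles: np.ndarray, motif_length: int) -> LocusMeta:
    obs = alleles[alleles != MISSING]
    if obs.size:
        lo, hi = int(obs.min()), int(obs.max())
    else:
        lo, hi = 1, 2
    # pad so simulated mutations have headroom, and keep min < max
    return LocusMeta(name, motif_length, (max(1, lo - 2), max(hi + 2, lo + 1)))


def _convert_bp(
    calls: np.ndarray, names: list[str], motif_lengths: list[int], report: IngestReport
) -> np.ndarray:
    """Convert fragment sizes (bp) to repeat units in place, per locus."""
    out = calls.copy()
    for j, (name, motif) in enumerate(zip(names, motif_lengths)):
        col = out[:, j, :]
        obs = col != MISSING
        if not obs.any():
            continue
        offset = int(col[obs].min()) % motif
        report.offsets[name] = offset
        shifted = (col[obs] - offset) / motif
        rounded = np.rint(shifted).astype(np.int64)
        off = shifted != rounded
        if off.any():
            report.rounded.append(
                f"{name}: {int(off.sum())} call(s) rounded to nearest repeat unit"
            )
        col[obs] = rounded
    return out


def read_genotypes(
    path: str | Path,
    dialect: str = "genepop",
    units: str = "repeat",
    motif_lengths: dict[str, int] | None = None,
) -> tuple[GenotypeMatrix, PopulationMap, IngestReport]:
    """Read a genotype file and its population labels.

    Returns ``(matrix, popmap, report)``; alleles are in repeat units on
    return regardless of the input units.
    """
    if dialect == "genepop":
        inds, pops, names, raw = _read_genepop(Path(path))
    elif dialect == "csv":
        inds, pops, names, raw = _read_csv(Path(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    report = IngestReport(units=units)
    motifs = [int((motif_lengths or {}).get(n, 2)) for n in names]
    if units == "bp":
        raw = _convert_bp(raw, names, motifs, report)
    elif units != "repeat":
        raise ValueError(f"unknown units {units!r}")

    loci = [_infer_locus_meta(n, raw[:, j, :], m) for j, (n, m) in enumerate(zip(names, motifs))]
    g = GenotypeMatrix(inds, loci, raw)
    pm = PopulationMap(dict(zip(inds, pops)))
    return g, pm, report


def _read_genepop(path: Path):
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        part = lines[i].strip()
        if part:
            names.extend(n.strip() for n in part.split(",") if n.strip())
        i += 1
    if not names:
        raise ParseError(f"{path}: no locus names before first 'pop' (line {i + 1})")

    inds: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_idx = 0
    width: int | None = None
    for lineno in range(i, len(lines)):
        line = lines[lineno].strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise ParseError(f"{path}: line {lineno + 1}: expected 'id , genotypes'")
        ind, _, geno = line.partition(",")
        fields = geno.split()
        if len(fields) != len(names):
            raise ParseError(
                f"{path}: line {lineno + 1}: {len(fields)} genotypes for {len(names)} loci"
            )
        row = []
        for name, tok in zip(names, fields):
            if not re.fullmatch(r"\d+", tok) or len(tok) % 2:
                raise ParseError(f"{path}: line {lineno + 1}: bad genotype {tok!r}")
            w = len(tok) // 2
            if width is None:
                width = w
            elif w != width:
                raise ParseError(
                    f"{path}: line {lineno + 1}: mixed {2 * width}- and {2 * w}-digit coding"
                )
            a, b = int(tok[:w]), int(tok[w:])
            if a == 0 or b == 0:  # allele 0 = missing (whole genotype)
                row.append((MISSING, MISSING))
            else:
                row.append((a, b))
        inds.append(ind.strip())
        pops.append(f"pop{pop_idx}")
        rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no individual records")
    return inds, pops, names, np.array(rows, dtype=np.int64)


def _read_csv(path: Path):
    with open(path, newline="") as fh:
        reader = _csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if len(header) < 4 or header[0] != "individual" or header[1] != "population":
            raise ParseError(f"{path}: line 1: expected individual,population,<locus>_1,...")
        names: list[str] = []
        for col in header[2::2]:
            if not col.endswith("_1"):
                raise ParseError(f"{path}: line 1: locus column {col!r} should end in _1")
            names.append(col[:-2])
        for name, col in zip(names, header[3::2]):
            if col != f"{name}_2":
                raise ParseError(f"{path}: line 1: expected {name}_2, found {col!r}")

        inds, pops, rows = [], [], []
        for lineno, rec in enumerate(reader, start=2):
            if not rec or not any(f.strip() for f in rec):
                continue
            if len(rec) != len(header):
                raise ParseError(f"{path}: line {lineno}: {len(rec)} fields, expected {len(header)}")
            inds.append(rec[0])
            pops.append(rec[1])
            row = []
            for k in range(2, len(rec), 2):
                a, b = rec[k].strip(), rec[k + 1].strip()
                if a.upper() == "NA" or b.upper() == "NA":
                    row.append((MISSING, MISSING))
                else:
                    try:
                        row.append((int(a), int(b)))
                    except ValueError:
                        raise ParseError(
                            f"{path}: line {lineno}: non-integer allele {a!r}/{b!r}"
                        ) from None
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no individual records")
    return inds, pops, names, np.array(rows, dtype=np.int64)


def write_genotypes(
    g: GenotypeMatrix,
    pops: PopulationMap,
    path: str | Path,
    dialect: str = "genepop",
    title: str = "edgepop export",
) -> None:
    """Write a genotype matrix (repeat units) in either dialect."""
    path = Path(path)
    if dialect == "genepop":
        width = 3 if max(hi for _, hi in (m.allele_range for m in g.loci)) > 99 else 2
        out = [title]
        out.extend(m.name for m in g.loci)
        labels = pops.labels_for(g)
        for p in range(labels.max() + 1):
            out.append("pop")
            for i in np.flatnonzero(labels == p):
                toks = []
                for j in range(g.n_loci):
                    a, b = g.calls[i, j]
                    if a == MISSING:
                        a = b = 0
                    toks.append(f"{a:0{width}d}{b:0{width}d}")
                out.append(f"{g.individuals[i]} , " + " ".join(toks))
        path.write_text("\n".join(out) + "\n")
    elif dialect == "csv":
        with open(path, "w", newline="") as fh:
            w = _csv.writer(fh)
            header = ["individual", "population"]
            for m in g.loci:
                header += [f"{m.name}_1", f"{m.name}_2"]
            w.writerow(header)
            for i, ind in enumerate(g.individuals):
                rec = [ind, pops.assignment[ind]]
                for j in range(g.n_loci):
                    a, b = g.calls[i, j]
                    rec += (["NA", "NA"] if a == MISSING else [int(a), int(b)])
                w.writerow(rec)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def read_fasta_alignment(paths: Iterable[str | Path]) -> list[AlignmentSet]:
    """Read one aligned FASTA per region; all files must share the same ids."""
    regions: list[AlignmentSet] = []
    for path in paths:
        path = Path(path)
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ParseError(f"{path}: no FASTA records")
        regions.append(
            AlignmentSet(
                ids=[r.id for r in records],
                sequences=[str(r.seq) for r in records],
                region=path.stem,
            )
        )
    if len(regions) > 1:
        ref = set(regions[0].ids)
        for reg in regions[1:]:
            diff = ref.symmetric_difference(reg.ids)
            if diff:
                raise ParseError(
                    f"id mismatch between regions {regions[0].region} and "
                    f"{reg.region}: {sorted(diff)}"
                )
    return regions


def write_fasta(a: AlignmentSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(a.ids, a.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def concatenate(regions: list[AlignmentSet]) -> AlignmentSet:
    """Concatenate per-region alignments id-wise into one alignment."""
    if not regions:
        raise ValueError("no regions to concatenate")
    first = regions[0]
    ids = list(first.ids)
    parts = {i: [s] for i, s in zip(first.ids, first.sequences)}
    for reg in regions[1:]:
        if set(reg.ids) != set(ids):
            raise ValueError(
                f"id set mismatch in region {reg.region}: "
                f"{sorted(set(reg.ids).symmetric_difference(ids))}"
            )
        lookup = dict(zip(reg.ids, reg.sequences))
        for i in ids:
            parts[i].append(lookup[i])
    name = "+".join(r.region for r in regions)
    return AlignmentSet(ids=ids, sequences=["".join(parts[i]) for i in ids], region=name)
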