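"""Motif-derived position-weight specifications and combinatorial peptide pools.

The central object is :class:`PositionWeightSpec`: for each flanking offset
around a central citrulline it lists the admitted residues together with
integer percent weights that sum to 100. Such a specification defines a
combinatorial sequence space (the immunogen pool), which can be sized in
closed form, enumerated exhaustively, or sampled with the stated per-position
weights.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .residues import CIT, STANDARD_AA_SET, mod_tag, parse_mod_tag


@dataclass(frozen=True)
class PositionWeightSpec:
    """Per-offset residue sets with integer percent weights.

    ``residues_at`` maps a flanking offset (offset 0 is the modified residue
    itself and never appears) to an ordered tuple of ``(residue, percent)``
    pairs. Percents at each offset must sum to exactly 100.
    """

    residues_at: dict[int, tuple[tuple[str, int], ...]]
    central_token: str = CIT

    def __post_init__(self) -> None:
        if 0 in self.residues_at:
            raise ValueError("offset 0 is the central modification, not a weighted position")
        for offset, pairs in self.residues_at.items():
            if not pairs:
                raise ValueError(f"offset {offset}: empty residue list")
            residues = [r for r, _ in pairs]
            if len(set(residues)) != len(residues):
                raise ValueError(f"offset {offset}: duplicate residues {residues}")
            bad = [r for r in residues if r not in STANDARD_AA_SET]
            if bad:
                raise ValueError(f"offset {offset}: non-standard residues {bad}")
            total = sum(p for _, p in pairs)
            if total != 100:
                raise ValueError(f"offset {offset}: percents sum to {total}, expected 100")

    @property
    def offsets(self) -> tuple[int, ...]:
        return tuple(sorted(self.residues_at))

    def residues(self, offset: int) -> tuple[str, ...]:
        return tuple(r for r, _ in self.residues_at[offset])

    def percents(self, offset: int) -> tuple[int, ...]:
        return tuple(p for _, p in self.residues_at[offset])

    def residue_set(self, offset: int) -> frozenset[str]:
        return frozenset(self.residues(offset))

    @property
    def central_index(self) -> int:
        """0-based index of the central residue in an assembled peptide."""
        return sum(1 for o in self.offsets if o < 0)

    @property
    def length(self) -> int:
        return len(self.offsets) + 1

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (offset, residue, percent)
            for offset in self.offsets
            for residue, percent in self.residues_at[offset]
        ]
        return pd.DataFrame(rows, columns=["offset", "residue", "percent"])


@dataclass(frozen=True)
class PeptideLibrary:
    """A materialized peptide pool.

    Peptides are strings with the central citrulline written as ``R``;
    ``central_index`` locates it (0-based).
    """

    spec: PositionWeightSpec
    peptides: tuple[str, ...]
    origin: str  # "enumerated" | "sampled"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.origin not in ("enumerated", "sampled"):
            raise ValueError(f"unknown origin {self.origin!r}")

    @property
    def size(self) -> int:
        return len(self.peptides)

    @property
    def central_index(self) -> int:
        return self.spec.central_index


def load_spec(path: str | Path) -> PositionWeightSpec:
    """Read a position-weight spec from TSV columns offset/residue/percent."""
    df = pd.read_csv(path, sep="\t")
    missing = {"offset", "residue", "percent"} - set(df.columns)
    if missing:
        raise ValueError(f"spec file {path}: missing columns {sorted(missing)}")
    residues_at: dict[int, tuple[tuple[str, int], ...]] = {}
    for offset, sub in df.groupby("offset", sort=True):
        residues_at[int(offset)] = tuple(
            (str(r), int(p)) for r, p in zip(sub["residue"], sub["percent"])
        )
    return PositionWeightSpec(residues_at)


def immunization_pool_spec() -> PositionWeightSpec:
    """The packaged position-weight table of the citrullination immunogen pool.

    Offsets -4..-1 and +1..+5 around the central citrulline, with residue-set
    sizes (4,4,4,4,4,4,4,5,6).
    """
    ref = resources.files("citmotif.data") / "immunization_pool_weights.tsv"
    with resources.as_file(ref) as path:
        return load_spec(path)


def library_size(spec: PositionWeightSpec) -> int:
    """Number of unique peptides in the combinatorial pool.

    Exact product of per-offset residue-set sizes (Python integers, so
    arbitrarily large products are safe). An empty spec has size 1: the bare
    central residue.
    """
    return math.prod(len(spec.residues_at[o]) for o in spec.offsets)


def _position_residues(spec: PositionWeightSpec) -> list[tuple[str, ...]]:
    """Residue choices per assembled-peptide position, central token included."""
    slots: list[tuple[str, ...]] = []
    inserted = False
    for offset in spec.offsets:
        if offset > 0 and not inserted:
            slots.append(("R",))
            inserted = True
        slots.append(spec.residues(offset))
    if not inserted:
        slots.append(("R",))
    return slots


def enumerate_library(
    spec: PositionWeightSpec, limit: int | None = None
) -> Iterator[str]:
    """Yield every peptide of the pool in offset-major lexicographic order.

    Residues iterate in the order listed by the spec, with the rightmost
    offset varying fastest. Stops after ``limit`` peptides when given.
    """
    it = ("".join(p) for p in itertools.product(*_position_residues(spec)))
    if limit is not None:
        it = itertools.islice(it, limit)
    return it


def sample_library(
    spec: PositionWeightSpec,
    n: int,
    seed: int,
    distinct: bool = False,
) -> PeptideLibrary:
    """Draw ``n`` peptides with per-offset residue probabilities = percent/100.

    By default sampling is with replacement — a synthesis pool is a mixture,
    so repeats are legitimate. ``distinct=True`` switches to rejection-based
    unique sampling (requires n <= library_size).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if distinct and n > library_size(spec):
        raise ValueError(f"cannot draw {n} distinct peptides from a space of {library_size(spec)}")

    offsets = spec.offsets
    central = spec.central_index

    def draw(m: int) -> list[str]:
        cols = []
        for offset in offsets:
            residues = np.array(spec.residues(offset))
            probs = np.array(spec.percents(offset), dtype=float) / 100.0
            cols.append(rng.choice(residues, size=m, p=probs))
        cols.insert(central, np.full(m, "R"))
        return ["".join(row) for row in zip(*cols)]

    if not distinct:
        peptides = tuple(draw(n))
    else:
        seen: dict[str, None] = {}
        while len(seen) < n:
            for pep in draw(n - len(seen)):
                if pep not in seen:
                    seen[pep] = None
                if len(seen) == n:
                    break
        peptides = tuple(seen)
    return PeptideLibrary(spec=spec, peptides=peptides, origin="sampled", seed=seed)


def export_library(library: PeptideLibrary, path: str | Path, dialect: str = "tsv") -> Path:
    """Write a library to disk.

    ``tsv``: columns index/sequence/modifications, the central citrulline
    rendered as ``R`` with a ``cit@<pos>`` annotation (1-based).
    ``fasta``: headers ``>pep<i> origin=<origin> mod=cit@<pos>``.
    """
    path = Path(path)
    if library.size == 0:
        raise ValueError("refusing to export an empty library")
    pos = library.central_index + 1
    tag = mod_tag(pos)
    if dialect == "tsv":
        df = pd.DataFrame(
            {
                "index": range(library.size),
                "sequence": library.peptides,
                "modifications": tag,
                "origin": library.origin,
            }
        )
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "fasta":
        with open(path, "w") as fh:
            for i, pep in enumerate(library.peptides):
                fh.write(f">pep{i} origin={library.origin} mod={tag}\n{pep}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def read_library(path: str | Path, dialect: str = "tsv") -> tuple[tuple[str, ...], int]:
    """Read back an exported library: (peptides, 0-based central index)."""
    path = Path(path)
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        peptides = tuple(df["sequence"].astype(str))
        mods = set(df["modifications"])
        if len(mods) != 1:
            raise ValueError("library with inconsistent modification annotations")
        _, pos = parse_mod_tag(mods.pop())
        return peptides, pos - 1
    if dialect == "fasta":
        peptides = []
        positions = set()
        with open(path) as fh:
            header = None
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith(">"):
                    header = line
                    for token in line[1:].split():
                        if token.startswith("mod="):
                            _, pos = parse_mod_tag(token[4:])
                            positions.add(pos)
                elif line:
                    if header is None:
                        raise ValueError("sequence before FASTA header")
                    peptides.append(line)
        if len(positions) != 1:
            raise ValueError("library with inconsistent modification annotations")
        return tuple(peptides), positions.pop() - 1
    raise ValueError(f"unknown dialect {dialect!r}")


def largest_remainder_percents(weights: Sequence[float]) -> list[int]:
    """Round non-negative weights to integer percents summing to exactly 100.

    Each weight's share is floored; the remaining points go to the largest
    fractional remainders (ties broken by position, i.e. first-listed wins).
    """
    weights = list(weights)
    total = float(sum(weights))
    if total <= 0:
        raise ValueError("weights must have a positive sum")
    raw = [100.0 * w / total for w in weights]
    floors = [int(math.floor(x)) for x in raw]
    shortfall = 100 - sum(floors)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - floors[i]), i))
    for i in order[:shortfall]:
        floors[i] += 1
    return floors
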