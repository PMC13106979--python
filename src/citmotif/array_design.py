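"""High-density peptide-microarray content and layout.

Two complementary 7-mer sets, each with a central citrulline (position 0):

* the motif set — the full Cartesian product of the immunization-pool
  residue sets at offsets -3..+3, except position +1 which carries all 20
  standard amino acids (20,480 cores for the packaged pool spec);
* the non-motif set — random combinations of the residues *absent* from the
  motif set at each position, with the +1 position additionally stripped of
  the motif-enriched residues G, S, A and D.

Cores are flanked with SG / SGS synthesis linkers; every peptide is spotted
in replicate alongside synthesis-control and blank spots, with seeded random
spot placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import itertools

import numpy as np
import pandas as pd

from .immunogen_design import PositionWeightSpec
from .residues import STANDARD_AA, STANDARD_AA_SET

CORE_OFFSETS: tuple[int, ...] = (-3, -2, -1, 1, 2, 3)
CORE_LENGTH = 7
CORE_CENTER = 3  # 0-based index of the citrulline in a 7-mer core
LINKER_N = "SG"
LINKER_C = "SGS"
CONTROL_SEQ = "EDKFVRYVD"

#: Motif-enriched residues at position +1, excluded from the non-motif set
#: there even though the motif set holds all 20 residues at that position.
PLUS1_EXCLUSIONS: frozenset[str] = frozenset("GSAD")


def build_motif_set(
    spec: PositionWeightSpec,
    offsets: Sequence[int] = CORE_OFFSETS,
    plus1_all20: bool = True,
) -> list[str]:
    """Enumerate every motif-conforming 7-mer core.

    Cartesian product of the spec's residue sets at ``offsets`` (weights are
    ignored — the array tests sequences, not frequencies); with
    ``plus1_all20`` the +1 position is widened to all 20 standard residues,
    in alphabetical order. Enumeration is offset-major with spec-listed
    residue order, hence deterministic and duplicate-free.
    """
    slots: list[tuple[str, ...]] = []
    for offset in offsets:
        if offset == 1 and plus1_all20:
            slots.append(tuple(STANDARD_AA))
            continue
        if offset not in spec.residues_at:
            raise KeyError(f"spec has no residue set at offset {offset}")
        slots.append(spec.residues(offset))
    central_slot = sum(1 for o in offsets if o < 0)
    slots.insert(central_slot, ("R",))
    return ["".join(p) for p in itertools.product(*slots)]


def complement_residues(
    spec: PositionWeightSpec,
    offset: int,
    exclusions: Iterable[str] = (),
    use_spec: bool = True,
) -> tuple[str, ...]:
    """Standard residues NOT admitted at ``offset``.

    With ``use_spec`` the spec's residue set at the offset is removed; for a
    position treated as all-20 on the array (``use_spec=False``) only the
    explicit ``exclusions`` are removed. Additional exclusions apply in both
    modes. Raises if nothing is left.
    """
    removed = set(exclusions)
    if use_spec:
        removed |= spec.residue_set(offset)
    complement = tuple(aa for aa in STANDARD_AA if aa not in removed)
    if not complement:
        raise ValueError(f"offset {offset}: empty complement")
    return complement


def nonmotif_complements(
    spec: PositionWeightSpec,
    offsets: Sequence[int] = CORE_OFFSETS,
    all20_offsets: Iterable[int] = (1,),
    all20_exclusions: Iterable[str] = PLUS1_EXCLUSIONS,
    global_exclusions: Iterable[str] = (),
) -> dict[int, tuple[str, ...]]:
    """Per-offset complement residue sets for the non-motif array group."""
    all20 = set(all20_offsets)
    out: dict[int, tuple[str, ...]] = {}
    for offset in offsets:
        if offset in all20:
            out[offset] = complement_residues(
                spec,
                offset,
                exclusions=set(all20_exclusions) | set(global_exclusions),
                use_spec=False,
            )
        else:
            out[offset] = complement_residues(
                spec, offset, exclusions=global_exclusions
            )
    return out


def build_non_motif_set(
    complements: Mapping[int, Sequence[str]],
    n: int,
    seed: int,
) -> list[str]:
    """Sample ``n`` unique cores, residues uniform over each offset's complement.

    Rejection sampling enforces sequence uniqueness; deterministic given the
    seed. Disjointness from any motif set built on the same spec holds by
    construction: the residue sets differ at every offset.
    """
    offsets = sorted(complements)
    space = math.prod(len(complements[o]) for o in offsets)
    if n > space:
        raise ValueError(f"cannot draw {n} unique cores from a space of {space}")
    rng = np.random.default_rng(seed)
    central_slot = sum(1 for o in offsets if o < 0)

    seen: dict[str, None] = {}
    while len(seen) < n:
        m = n - len(seen)
        cols = [
            rng.choice(np.array(complements[o]), size=m) for o in offsets
        ]
        cols.insert(central_slot, np.full(m, "R"))
        for core in ("".join(row) for row in zip(*cols)):
            if core not in seen:
                seen[core] = None
                if len(seen) == n:
                    break
    return list(seen)


def add_linkers(core: str) -> str:
    """Flank a 7-mer core with the SG / SGS synthesis linkers (length 12)."""
    if len(core) != CORE_LENGTH:
        raise ValueError(f"core must be {CORE_LENGTH} residues, got {len(core)}")
    if core[CORE_CENTER] != "R":
        raise ValueError("core center must be the citrullinated R")
    return LINKER_N + core + LINKER_C


@dataclass(frozen=True)
class ArrayDesign:
    """Peptide content plus randomized spot layout.

    ``peptides`` columns: peptide_id, group (cit_motif / cit_non_motif),
    core, synthesis_sequence. ``layout`` columns: spot_index, kind
    (peptide / control / blank), peptide_id (empty for blanks).
    """

    peptides: pd.DataFrame
    layout: pd.DataFrame
    replicates: int
    control_seq: str
    n_controls: int
    n_blanks: int
    seed: int

    @property
    def n_spots(self) -> int:
        return len(self.layout)

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    def mapping(self) -> pd.DataFrame:
        """Layout joined with peptide annotations (one row per spot)."""
        df = self.layout.merge(self.peptides, on="peptide_id", how="left")
        nonpep = df["kind"] != "peptide"
        df.loc[nonpep, "group"] = df.loc[nonpep, "kind"]
        df["core"] = df["core"].fillna("")
        df["synthesis_sequence"] = df["synthesis_sequence"].fillna("")
        df.loc[df["kind"] == "control", "synthesis_sequence"] = self.control_seq
        return df

    def write(self, out_dir: str | Path, grid_cols: int | None = None) -> dict[str, Path]:
        """Write peptides.tsv and a GAL-like layout.tsv (block/row/col grid)."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        peptides_path = out_dir / "peptides.tsv"
        layout_path = out_dir / "layout.tsv"
        self.peptides.to_csv(peptides_path, sep="\t", index=False)
        gal = self.mapping()
        ncols = grid_cols or int(math.ceil(math.sqrt(self.n_spots)))
        gal.insert(1, "block", 1)
        gal.insert(2, "row", gal["spot_index"] // ncols + 1)
        gal.insert(3, "col", gal["spot_index"] % ncols + 1)
        gal.to_csv(layout_path, sep="\t", index=False)
        return {"peptides": peptides_path, "layout": layout_path}


def layout_array(
    motif_set: Sequence[str],
    non_motif_set: Sequence[str],
    replicates: int = 3,
    control_seq: str = CONTROL_SEQ,
    n_controls: int = 2495,
    n_blanks: int = 2500,
    seed: int = 0,
) -> ArrayDesign:
    """Assemble the full array: replicated peptide spots plus controls and
    blanks in a seeded random placement."""
    overlap = set(motif_set) & set(non_motif_set)
    if overlap:
        raise ValueError(f"motif and non-motif sets overlap: {sorted(overlap)[:5]} ...")

    records = [("M%06d" % i, "cit_motif", core) for i, core in enumerate(motif_set)]
    records += [("N%06d" % i, "cit_non_motif", core) for i, core in enumerate(non_motif_set)]
    peptides = pd.DataFrame(records, columns=["peptide_id", "group", "core"])
    if peptides["core"].duplicated().any():
        raise ValueError("duplicate cores within a peptide set")
    peptides["synthesis_sequence"] = [add_linkers(c) for c in peptides["core"]]

    kinds = np.concatenate(
        [
            np.repeat("peptide", len(peptides) * replicates),
            np.repeat("control", n_controls),
            np.repeat("blank", n_blanks),
        ]
    )
    ids = np.concatenate(
        [
            np.tile(peptides["peptide_id"].to_numpy(), replicates),
            np.repeat("CTRL", n_controls),
            np.repeat("", n_blanks),
        ]
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(kinds))
    layout = pd.DataFrame(
        {
            "spot_index": np.arange(len(kinds)),
            "kind": kinds[order],
            "peptide_id": ids[order],
        }
    )
    return ArrayDesign(
        peptides=peptides,
        layout=layout,
        replicates=replicates,
        control_seq=control_seq,
        n_controls=n_controls,
        n_blanks=n_blanks,
        seed=seed,
    )


def read_design_mapping(path: str | Path) -> pd.DataFrame:
    """Read back a written layout.tsv as a spot -> peptide mapping."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    needed = {"spot_index", "kind", "peptide_id"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"design mapping {path}: missing columns {sorted(missing)}")
    return df
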