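"""Modification-level summaries over peptide-level MS search results.

Consumes peptide tables exported by any search engine (sequence, intensity,
modification string) and reports what fraction of peptides — and of summed
intensity — carries a given modification, both relative to peptides that
contain the target residue and relative to all peptides. Also recomputes
modification monoisotopic mass deltas from elemental composition.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

# CODATA-style monoisotopic atomic masses (Da)
MASS_H = 1.0078250319
MASS_C = 12.0
MASS_N = 14.0030740052
MASS_O = 15.9949146221

#: Elemental composition change per modification type.
_DELTAS: dict[str, dict[str, int]] = {
    # Arg -> citrulline: the guanidinium NH is replaced by a carbonyl O
    "citrullination": {"O": +1, "N": -1, "H": -1},
    # Asn/Gln deamidation: identical composition change (the MS ambiguity)
    "deamidation": {"O": +1, "N": -1, "H": -1},
    # Lys + cyanate -> homocitrulline (carbamylation)
    "carbamylation": {"H": +1, "C": +1, "N": +1, "O": +1},
}

#: Residue each modification is chemically confined to (None = unconstrained).
MOD_RESIDUE: dict[str, str | None] = {
    "citrullination": "R",
    "carbamylation": "K",
    "deamidation": None,  # N or Q; not enforced at parse level
    "other": None,
}

_MOD_ALIASES = {
    "cit": "citrullination",
    "citrullination": "citrullination",
    "deam": "deamidation",
    "deamidation": "deamidation",
    "carbamyl": "carbamylation",
    "carbamylation": "carbamylation",
}

_MOD_TOKEN = re.compile(r"^(\d+)([A-Z])\(([^)]+)\)$")


def mod_delta(mod_type: str) -> float:
    """Monoisotopic mass shift of a modification, from elemental composition."""
    try:
        comp = _DELTAS[mod_type]
    except KeyError:
        raise ValueError(f"unknown modification type {mod_type!r}") from None
    masses = {"H": MASS_H, "C": MASS_C, "N": MASS_N, "O": MASS_O}
    return sum(count * masses[el] for el, count in comp.items())


@dataclass(frozen=True)
class Modification:
    residue: str
    position: int  # 1-based offset in the peptide
    mod_type: str


@dataclass(frozen=True)
class PeptideRecord:
    sequence: str
    intensity: float
    modifications: tuple[Modification, ...] = ()
    flags: tuple[str, ...] = ()  # residue-type / position violations

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")

    def has_mod(self, mod_type: str) -> bool:
        return any(m.mod_type == mod_type for m in self.modifications)

    def contains(self, residue: str) -> bool:
        return residue in self.sequence


def parse_modifications(
    sequence: str, text: str
) -> tuple[tuple[Modification, ...], tuple[str, ...]]:
    """Parse a modification string like ``"5R(cit);7K(carbamyl)"``.

    Each token is <1-based position><residue>(<type>); tokens are
    semicolon-separated. Violations (position out of range, residue mismatch
    with the sequence, chemically impossible residue for the type) are
    collected as flags, not fatal; a malformed token is a ValueError.
    """
    text = (text or "").strip()
    if not text:
        return (), ()
    mods: list[Modification] = []
    flags: list[str] = []
    for token in text.split(";"):
        token = token.strip()
        m = _MOD_TOKEN.match(token)
        if not m:
            raise ValueError(f"malformed modification token {token!r}")
        pos, residue, raw_type = int(m.group(1)), m.group(2), m.group(3).lower()
        mod_type = _MOD_ALIASES.get(raw_type, "other")
        if not 1 <= pos <= len(sequence):
            flags.append(f"position {pos} outside peptide of length {len(sequence)}")
            continue
        if sequence[pos - 1] != residue:
            flags.append(f"residue {residue} at {pos} does not match sequence {sequence[pos - 1]}")
        required = MOD_RESIDUE.get(mod_type)
        if required is not None and residue != required:
            flags.append(f"{mod_type} on {residue}{pos} (expected {required})")
        mods.append(Modification(residue=residue, position=pos, mod_type=mod_type))
    return tuple(mods), tuple(flags)


def read_peptide_table(path: str | Path) -> list[PeptideRecord]:
    """Read a peptide-level TSV with columns sequence, intensity, modifications.

    Malformed modification strings are collected per row and reported
    together at the end rather than aborting on the first.
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = {"sequence", "intensity", "modifications"} - set(df.columns)
    if missing:
        raise ValueError(f"peptide table {path}: missing columns {sorted(missing)}")
    records: list[PeptideRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        seq = str(row["sequence"])
        try:
            mods, flags = parse_modifications(seq, str(row["modifications"]))
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
            continue
        records.append(
            PeptideRecord(
                sequence=seq,
                intensity=float(row["intensity"]),
                modifications=mods,
                flags=flags,
            )
        )
    if errors:
        raise ValueError(f"{path}: {len(errors)} malformed rows: " + "; ".join(errors[:5]))
    return records


@dataclass(frozen=True)
class ModificationSummary:
    """Paired count- and intensity-based modification levels.

    Percentages on 0-100; target-based fields are None when no peptide
    contains the target residue (undefined, not zero).
    """

    mod_type: str
    target_residue: str
    n_peptides: int
    n_target: int
    n_modified: int
    intensity_total: float
    intensity_target: float
    intensity_modified: float
    pct_target_peptides_modified: float | None
    pct_all_peptides_modified: float
    pct_target_intensity_modified: float | None
    pct_all_intensity_modified: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def percent_modified(
    records: Sequence[PeptideRecord], mod_type: str, target_residue: str
) -> ModificationSummary:
    """Fraction of peptides (and intensity) carrying a modification.

    A peptide counts as modified if it carries >= 1 modification of the
    queried type, regardless of how many sites. Reported relative to
    target-residue-containing peptides and to all peptides, by count and by
    summed intensity.
    """
    if mod_type not in MOD_RESIDUE:
        raise ValueError(f"unknown modification type {mod_type!r}")
    if not records:
        raise ValueError("need at least one peptide record")
    n = len(records)
    target = [r for r in records if r.contains(target_residue)]
    modified = [r for r in records if r.has_mod(mod_type)]
    i_total = sum(r.intensity for r in records)
    i_target = sum(r.intensity for r in target)
    i_mod = sum(r.intensity for r in modified)

    def pct(num: float, den: float) -> float | None:
        return 100.0 * num / den if den > 0 else None

    return ModificationSummary(
        mod_type=mod_type,
        target_residue=target_residue,
        n_peptides=n,
        n_target=len(target),
        n_modified=len(modified),
        intensity_total=i_total,
        intensity_target=i_target,
        intensity_modified=i_mod,
        pct_target_peptides_modified=pct(len(modified), len(target)),
        pct_all_peptides_modified=100.0 * len(modified) / n,
        pct_target_intensity_modified=pct(i_mod, i_target),
        pct_all_intensity_modified=pct(i_mod, i_total) if i_total > 0 else 0.0,
    )
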