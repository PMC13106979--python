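"""Amino-acid alphabet and citrulline text conventions.

Peptide sequences are stored as plain strings of one-letter codes. A
citrullinated arginine is written as ``R`` in the sequence itself; the
modification is carried out-of-band as a 1-based position annotation
(``cit@5``) or inline as ``R[cit]`` for single-column formats, so no
information is lost in either direction.
"""

from __future__ import annotations

import re

#: The 20 standard amino acids, alphabetical by one-letter code.
STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"
STANDARD_AA_SET: frozenset[str] = frozenset(STANDARD_AA)

#: Pad token used for window positions beyond a protein terminus.
PAD: str = "-"

#: Internal token for a citrulline residue.
CIT: str = "CIT"

_INLINE_RE = re.compile(r"R\[cit\]")


def mod_tag(position: int, mod: str = "cit") -> str:
    """Annotation for a modification at a 1-based sequence position."""
    return f"{mod}@{position}"


def parse_mod_tag(tag: str) -> tuple[str, int]:
    mod, _, pos = tag.partition("@")
    return mod, int(pos)


def render_inline(sequence: str, cit_positions: tuple[int, ...]) -> str:
    """Render citrulline positions inline, e.g. ``GDSR[cit]GDE``.

    ``cit_positions`` are 1-based indices into ``sequence``; each must hold
    an arginine.
    """
    out = []
    cit = set(cit_positions)
    for i, aa in enumerate(sequence, start=1):
        if i in cit:
            if aa != "R":
                raise ValueError(f"citrulline annotation at {i} on non-R residue {aa!r}")
            out.append("R[cit]")
        else:
            out.append(aa)
    return "".join(out)


def parse_inline(text: str) -> tuple[str, tuple[int, ...]]:
    """Inverse of :func:`render_inline`."""
    sequence = []
    positions = []
    i = 0
    while i < len(text):
        m = _INLINE_RE.match(text, i)
        if m:
            sequence.append("R")
            positions.append(len(sequence))
            i = m.end()
        else:
            sequence.append(text[i])
            i += 1
    return "".join(sequence), tuple(positions)
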