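"""Position-specific residue enrichment around modification sites.

Given a proteome and a list of modified positions (citrullinated arginines,
homocitrullinated lysines, ...), this module extracts flanking-residue
windows and scores every (offset, residue) cell with exact binomial tail
probabilities against a background model — the statistic popularized by the
pLogo sequence-logo tool. Significance uses a Bonferroni correction over all
20 residues at every scored offset; the exported score is the signed
-log10 of the smaller tail (positive = over-represented).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.stats import binom

from .immunogen_design import PositionWeightSpec, largest_remainder_percents
from .residues import PAD, STANDARD_AA, STANDARD_AA_SET

_P_FLOOR = 1e-300  # keeps -log10 finite when a tail underflows


# ---------------------------------------------------------------------------
# input plumbing


def read_proteome(path: str | Path) -> dict[str, str]:
    """Read a FASTA proteome into {protein_id: sequence}.

    The id is the first whitespace-delimited token of each header. Duplicate
    ids and empty/non-FASTA files are errors; non-standard letters are kept
    in the sequences (they are ignored downstream by counting code).
    """
    path = Path(path)
    proteome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in proteome:
            raise ValueError(f"duplicate protein id {record.id!r} in {path}")
        proteome[record.id] = str(record.seq).upper()
    if not proteome:
        raise ValueError(f"{path}: no FASTA records found")
    return proteome


def read_sites(path: str | Path) -> list[tuple[str, int, str]]:
    """Read a modification-site TSV: protein_id, position (1-based), residue."""
    df = pd.read_csv(path, sep="\t")
    missing = {"protein_id", "position", "residue"} - set(df.columns)
    if missing:
        raise ValueError(f"site table {path}: missing columns {sorted(missing)}")
    return [
        (str(p), int(pos), str(r))
        for p, pos, r in zip(df["protein_id"], df["position"], df["residue"])
    ]


# ---------------------------------------------------------------------------
# windows


@dataclass(frozen=True)
class SiteWindow:
    """Flanking residues around one modified site.

    ``offsets`` are -W..-1, +1..+W; the site itself (offset 0) is stored as
    ``central_residue``, never among the flanks. Positions beyond a protein
    terminus carry the pad token.
    """

    protein_id: str
    site_pos: int  # 1-based
    central_residue: str
    offsets: tuple[int, ...]
    residues: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.residues):
            raise ValueError("offsets and residues differ in length")
        if 0 in self.offsets:
            raise ValueError("offset 0 belongs to central_residue, not the flanks")

    def residue_at(self, offset: int) -> str:
        return self.residues[self.offsets.index(offset)]


@dataclass(frozen=True)
class WindowExtraction:
    windows: tuple[SiteWindow, ...]
    mismatched_sites: tuple[tuple[str, int, str, str], ...]  # (id, pos, expected, found)

    @property
    def n_mismatched(self) -> int:
        return len(self.mismatched_sites)


def extract_windows(
    proteome: dict[str, str],
    sites: Iterable[tuple[str, int, str]],
    W: int = 5,
) -> WindowExtraction:
    """Extract +-W flanking windows for each (protein_id, position, residue).

    Sites whose stated residue does not match the sequence are excluded and
    reported, not fatal; an unknown protein id is fatal. Out-of-range
    positions within the protein raise as well.
    """
    if W < 1:
        raise ValueError("W must be >= 1")
    offsets = tuple(list(range(-W, 0)) + list(range(1, W + 1)))
    windows: list[SiteWindow] = []
    mismatched: list[tuple[str, int, str, str]] = []
    for protein_id, site_pos, expected in sites:
        try:
            seq = proteome[protein_id]
        except KeyError:
            raise KeyError(f"unknown protein id {protein_id!r}") from None
        if not 1 <= site_pos <= len(seq):
            raise ValueError(
                f"{protein_id}: site position {site_pos} outside 1..{len(seq)}"
            )
        found = seq[site_pos - 1]
        if found != expected:
            mismatched.append((protein_id, site_pos, expected, found))
            continue
        residues = tuple(
            seq[i - 1] if 1 <= i <= len(seq) else PAD
            for i in (site_pos + o for o in offsets)
        )
        windows.append(
            SiteWindow(
                protein_id=protein_id,
                site_pos=site_pos,
                central_residue=found,
                offsets=offsets,
                residues=residues,
            )
        )
    return WindowExtraction(tuple(windows), tuple(mismatched))


# ---------------------------------------------------------------------------
# background models


@dataclass(frozen=True)
class BackgroundModel:
    """Position-independent residue frequencies.

    Probabilities cover the 20 standard amino acids, each strictly positive
    (zero counts are floored at a 0.5 pseudocount) and summing to 1.
    """

    residue_freq: dict[str, float]
    source: str  # "proteome_global" | "window_empirical"
    residue_counts: dict[str, int]

    def __post_init__(self) -> None:
        total = sum(self.residue_freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total}, expected 1")
        if any(q <= 0 for q in self.residue_freq.values()):
            raise ValueError("background frequencies must be strictly positive")

    def q(self, offset: int, residue: str) -> float:
        return self.residue_freq[residue]


@dataclass(frozen=True)
class PositionalBackground:
    """Per-offset residue frequencies (used when the tested sequence space is
    itself non-uniform, e.g. enrichment of array binders against all tested
    peptides)."""

    freq: dict[int, dict[str, float]]
    source: str = "positional"

    def q(self, offset: int, residue: str) -> float:
        return self.freq[offset][residue]


def _counts_to_freq(counts: Counter[str]) -> tuple[dict[str, float], dict[str, int]]:
    kept = {aa: counts.get(aa, 0) for aa in STANDARD_AA}
    if sum(kept.values()) == 0:
        raise ValueError("no standard residues to build a background from")
    # pseudocount floor so every q is usable as a binomial parameter
    adjusted = {aa: max(c, 0.5) for aa, c in kept.items()}
    total = sum(adjusted.values())
    return {aa: c / total for aa, c in adjusted.items()}, kept


def background_from_proteome(proteome: dict[str, str]) -> BackgroundModel:
    """Global residue frequencies of a proteome (non-standard letters excluded)."""
    counts: Counter[str] = Counter()
    for seq in proteome.values():
        counts.update(aa for aa in seq if aa in STANDARD_AA_SET)
    freq, kept = _counts_to_freq(counts)
    return BackgroundModel(residue_freq=freq, source="proteome_global", residue_counts=kept)


def background_from_windows(windows: Sequence[SiteWindow]) -> BackgroundModel:
    """Residue frequencies over all non-pad flanking positions of the windows."""
    counts: Counter[str] = Counter()
    for w in windows:
        counts.update(aa for aa in w.residues if aa in STANDARD_AA_SET)
    freq, kept = _counts_to_freq(counts)
    return BackgroundModel(residue_freq=freq, source="window_empirical", residue_counts=kept)


# ---------------------------------------------------------------------------
# the binomial statistic


def binomial_tail(k: int, n: int, q: float, tail: str = "over") -> float:
    """Exact binomial tail probability.

    ``over``: P(X >= k); ``under``: P(X <= k) for X ~ Binomial(n, q).
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < q < 1:
        raise ValueError(f"need 0 < q < 1, got q={q}")
    if tail == "over":
        return float(binom.sf(k - 1, n, q))
    if tail == "under":
        return float(binom.cdf(k, n, q))
    raise ValueError(f"unknown tail {tail!r}")


@dataclass(frozen=True)
class EnrichmentTable:
    """Per-(offset, residue) enrichment statistics.

    ``table`` columns: offset, residue, k, n, q, p_over, p_under, score,
    significant. Score sign convention: positive = over-represented with
    magnitude -log10(p_over); negative = under-represented with magnitude
    -log10(p_under). Significance compares the smaller tail to
    alpha / n_tests under Bonferroni (n_tests = 20 x scored offsets).
    """

    table: pd.DataFrame
    alpha: float
    n_tests: int
    correction: str

    def cell(self, offset: int, residue: str) -> pd.Series:
        sub = self.table[(self.table.offset == offset) & (self.table.residue == residue)]
        if len(sub) != 1:
            raise KeyError(f"no cell for offset {offset}, residue {residue}")
        return sub.iloc[0]

    def significant_over(self, offset: int) -> list[str]:
        sub = self.table[
            (self.table.offset == offset)
            & self.table.significant
            & (self.table.score > 0)
        ]
        return list(sub.residue)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        return path


def compute_enrichment(
    windows: Sequence[SiteWindow],
    background: BackgroundModel | PositionalBackground,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> EnrichmentTable:
    """Binomial enrichment of every residue at every window offset.

    For offset p and residue r: k = windows carrying r at p, n_p = windows
    with a standard (non-pad) residue at p, q = background probability. Both
    tails are computed exactly; offsets where every window is padded are
    reported with n = 0 and no tests.
    """
    if not windows:
        raise ValueError("need at least one window")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")

    offsets = windows[0].offsets
    for w in windows:
        if w.offsets != offsets:
            raise ValueError("windows have inconsistent offsets")

    counts: dict[int, Counter[str]] = {o: Counter() for o in offsets}
    for w in windows:
        for o, aa in zip(w.offsets, w.residues):
            if aa in STANDARD_AA_SET:
                counts[o][aa] += 1

    n_by_offset = {o: sum(counts[o].values()) for o in offsets}
    scored_offsets = [o for o in offsets if n_by_offset[o] > 0]
    n_tests = len(STANDARD_AA) * len(scored_offsets)
    threshold = alpha / n_tests if correction == "bonferroni" else alpha

    rows = []
    for o in offsets:
        n = n_by_offset[o]
        for aa in STANDARD_AA:
            k = counts[o].get(aa, 0)
            q = background.q(o, aa)
            rows.append((o, aa, k, n, q))
    df = pd.DataFrame(rows, columns=["offset", "residue", "k", "n", "q"])

    tested = df["n"].to_numpy() > 0
    k = df["k"].to_numpy()
    n = df["n"].to_numpy()
    q = df["q"].to_numpy()
    p_over = np.ones(len(df))
    p_under = np.ones(len(df))
    p_over[tested] = binom.sf(k[tested] - 1, n[tested], q[tested])
    p_under[tested] = binom.cdf(k[tested], n[tested], q[tested])
    df["p_over"] = p_over
    df["p_under"] = p_under

    over_side = p_over <= p_under
    score = np.where(
        over_side,
        -np.log10(np.maximum(p_over, _P_FLOOR)),
        np.log10(np.maximum(p_under, _P_FLOOR)),
    )
    df["score"] = np.where(tested, score, 0.0)
    df["significant"] = tested & (np.minimum(p_over, p_under) < threshold)

    return EnrichmentTable(table=df, alpha=alpha, n_tests=n_tests, correction=correction)


def select_motif_residues(
    table: EnrichmentTable, alpha: float | None = None
) -> PositionWeightSpec:
    """Build a position-weight spec from significantly over-represented cells.

    Per offset, the selected residues' observed foreground frequencies are
    renormalized over the selection and rounded to integer percents with the
    largest-remainder method (so they sum to exactly 100). Offsets with no
    significant over-representation are omitted; an empty spec is valid.
    """
    if alpha is not None and alpha != table.alpha:
        raise ValueError(
            f"table was computed at alpha={table.alpha}, selection requested {alpha}"
        )
    residues_at: dict[int, tuple[tuple[str, int], ...]] = {}
    for offset, sub in table.table.groupby("offset", sort=True):
        hits = sub[sub.significant & (sub.score > 0)].sort_values(
            ["k", "residue"], ascending=[False, True]
        )
        if hits.empty:
            continue
        percents = largest_remainder_percents(hits["k"].tolist())
        residues_at[int(offset)] = tuple(
            (str(r), int(p)) for r, p in zip(hits["residue"], percents)
        )
    return PositionWeightSpec(residues_at)
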