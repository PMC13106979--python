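"""Peptide-microarray signal analysis.

Workflow: read per-spot fluorescence ("F635 Mean" readout) from a GPR-style
or plain TSV table, join spots to the array design, average replicates per
unique peptide, compare group signal distributions, pick the top quantile of
mean signal as "strong binders" (irrespective of design group), and
reconstruct the recognized motif by binomial enrichment of the binders
against the positional residue composition of ALL tested peptides.

The enrichment background is deliberately the tested library, not a
proteome: the array's sequence space is heavily non-uniform by design, so a
proteome background would simply re-discover the library composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .array_design import ArrayDesign, CORE_CENTER, CORE_OFFSETS
from .motif_enrichment import (
    EnrichmentTable,
    PositionalBackground,
    SiteWindow,
    compute_enrichment,
)
from .residues import STANDARD_AA


# ---------------------------------------------------------------------------
# reading spot tables


def _parse_gpr(path: Path) -> pd.DataFrame:
    """Parse a text GPR (GenePix/Mapix results) file by header keys.

    Skips the ATF preamble and locates the tab-separated header row that
    contains "F635 Mean"; only header-keyed columns are interpreted.
    """
    header_idx = None
    with open(path) as fh:
        for i, line in enumerate(fh):
            if "F635 Mean" in line:
                header_idx = i
                break
    if header_idx is None:
        raise ValueError(f'{path}: no header row with an "F635 Mean" column')
    df = pd.read_csv(
        path, sep="\t", skiprows=header_idx, quotechar='"', keep_default_na=False
    )
    df.columns = [c.strip().strip('"') for c in df.columns]
    return df


def read_spot_table(
    path: str | Path,
    dialect: str = "tsv",
    design: ArrayDesign | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Read per-spot fluorescence into a normalized spot table.

    Returns columns spot_index, peptide_id, kind, group, core, f635_mean,
    flag. ``design`` (an :class:`ArrayDesign` or its mapping frame) supplies
    spot identities via spot_index; without it, identities must be carried by
    the signal file itself (ID/kind columns). Unmatched spots are counted in
    ``df.attrs["n_unmatched"]``.
    """
    path = Path(path)
    if dialect == "gpr":
        raw = _parse_gpr(path)
        f635 = raw["F635 Mean"]
        flag = raw["Flags"] if "Flags" in raw.columns else 0
        spot_index = raw["Index"] if "Index" in raw.columns else np.arange(len(raw))
        pid = raw["ID"] if "ID" in raw.columns else raw.get("Name", "")
        df = pd.DataFrame(
            {
                "spot_index": np.asarray(spot_index, dtype=int),
                "peptide_id": np.asarray(pid, dtype=str),
                "f635_mean": np.asarray(f635, dtype=float),
                "flag": np.asarray(flag, dtype=int) if not np.isscalar(flag) else 0,
            }
        )
    elif dialect == "tsv":
        raw = pd.read_csv(path, sep="\t", keep_default_na=False)
        if "f635_mean" not in raw.columns:
            raise ValueError(f"{path}: missing f635_mean column")
        df = pd.DataFrame(
            {
                "spot_index": raw["spot_index"].astype(int)
                if "spot_index" in raw.columns
                else np.arange(len(raw)),
                "peptide_id": raw["peptide_id"].astype(str)
                if "peptide_id" in raw.columns
                else "",
                "f635_mean": raw["f635_mean"].astype(float),
                "flag": raw["flag"].astype(int) if "flag" in raw.columns else 0,
            }
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if (df["f635_mean"] < 0).any():
        raise ValueError(f"{path}: negative fluorescence values")
    if df["spot_index"].duplicated().any():
        raise ValueError(f"{path}: duplicate spot indices")

    mapping: pd.DataFrame | None
    if isinstance(design, ArrayDesign):
        mapping = design.mapping()
    else:
        mapping = design
    n_unmatched = 0
    if mapping is not None:
        cols = [c for c in ("spot_index", "kind", "group", "peptide_id", "core") if c in mapping.columns]
        joined = df.drop(columns=["peptide_id"]).merge(
            mapping[cols], on="spot_index", how="left"
        )
        n_unmatched = int(joined["kind"].isna().sum())
        joined["kind"] = joined["kind"].fillna("unknown")
        joined["group"] = joined["group"].fillna("unknown")
        joined["peptide_id"] = joined["peptide_id"].fillna("")
        if "core" not in joined.columns:
            joined["core"] = ""
        joined["core"] = joined["core"].fillna("")
        df = joined
    else:
        df["kind"] = np.where(
            df["peptide_id"] == "", "blank",
            np.where(df["peptide_id"] == "CTRL", "control", "peptide"),
        )
        df["group"] = df["kind"]
        df["core"] = ""
    df = df[["spot_index", "peptide_id", "kind", "group", "core", "f635_mean", "flag"]]
    df.attrs["n_unmatched"] = n_unmatched
    return df


# ---------------------------------------------------------------------------
# replicate summaries and group statistics


def summarize_replicates(spots: pd.DataFrame) -> pd.DataFrame:
    """Mean F635 signal per unique peptide over valid (unflagged) replicates.

    Returns columns peptide_id, core, group, mean_signal, n_valid, cv;
    peptides whose replicates are all flagged are excluded and counted in
    ``attrs["n_excluded"]``.
    """
    pep = spots[spots["kind"] == "peptide"]
    valid = pep[pep["flag"] == 0]
    grouped = valid.groupby("peptide_id", sort=True)
    summary = grouped.agg(
        core=("core", "first"),
        group=("group", "first"),
        mean_signal=("f635_mean", "mean"),
        n_valid=("f635_mean", "size"),
        sd=("f635_mean", "std"),
    ).reset_index()
    summary["cv"] = np.where(
        summary["mean_signal"] > 0, summary["sd"].fillna(0.0) / summary["mean_signal"], np.nan
    )
    summary = summary.drop(columns=["sd"])
    n_excluded = pep["peptide_id"].nunique() - len(summary)
    summary.attrs["n_excluded"] = int(n_excluded)
    return summary


def group_distributions(
    summaries: pd.DataFrame, blank_spots: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-group signal distribution statistics (n, median, quartiles).

    Peptide groups are summarized from per-peptide mean signals; blank spots,
    if given, from their raw spot values (blanks have no replicate identity).
    """
    rows = []
    for group, sub in summaries.groupby("group", sort=True):
        x = sub["mean_signal"].to_numpy()
        rows.append(_dist_row(group, x))
    if blank_spots is not None:
        blanks = blank_spots[blank_spots["kind"] == "blank"]["f635_mean"].to_numpy()
        rows.append(_dist_row("blank", blanks))
    return pd.DataFrame(rows, columns=["group", "n", "median", "q1", "q3"])


def _dist_row(group: str, x: np.ndarray) -> tuple:
    if len(x) == 0:
        return (group, 0, np.nan, np.nan, np.nan)
    return (
        group,
        len(x),
        float(np.median(x)),
        float(np.quantile(x, 0.25)),
        float(np.quantile(x, 0.75)),
    )


# ---------------------------------------------------------------------------
# strong binders


@dataclass(frozen=True)
class BinderSelection:
    """Top-quantile peptides by mean signal, across all design groups."""

    quantile: float
    threshold: float
    peptide_ids: tuple[str, ...]
    n_selected: int

    def __post_init__(self) -> None:
        if self.n_selected != len(self.peptide_ids):
            raise ValueError("n_selected inconsistent with selection")


def select_strong_binders(summaries: pd.DataFrame, q: float = 0.25) -> BinderSelection:
    """Select the top fraction ``q`` of peptides by mean signal.

    Peptides are ranked by mean_signal descending; exactly floor(q * n) are
    taken, with ties at the boundary resolved by ascending peptide id so the
    selection is deterministic. Selection ignores group membership.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    n = len(summaries)
    n_selected = math.floor(q * n)
    if n_selected < 1:
        raise ValueError(f"quantile {q} of {n} peptides selects nothing")
    ranked = summaries.sort_values(
        ["mean_signal", "peptide_id"], ascending=[False, True], kind="mergesort"
    )
    chosen = ranked.head(n_selected)
    return BinderSelection(
        quantile=q,
        threshold=float(chosen["mean_signal"].iloc[-1]),
        peptide_ids=tuple(chosen["peptide_id"]),
        n_selected=n_selected,
    )


# ---------------------------------------------------------------------------
# motif reconstruction from binders


def _cores_to_windows(cores: Sequence[str], offsets: Sequence[int]) -> list[SiteWindow]:
    offsets = tuple(offsets)
    windows = []
    for i, core in enumerate(cores):
        residues = tuple(core[CORE_CENTER + o] for o in offsets)
        windows.append(
            SiteWindow(
                protein_id=f"core{i}",
                site_pos=CORE_CENTER + 1,
                central_residue=core[CORE_CENTER],
                offsets=offsets,
                residues=residues,
            )
        )
    return windows


def positional_background_from_cores(
    cores: Sequence[str], offsets: Sequence[int] = CORE_OFFSETS
) -> PositionalBackground:
    """Per-offset residue frequencies over a set of tested cores, with a 0.5
    pseudocount so every probability is strictly positive."""
    freq: dict[int, dict[str, float]] = {}
    for o in offsets:
        col = [core[CORE_CENTER + o] for core in cores]
        counts = pd.Series(col).value_counts().to_dict()
        adjusted = {aa: max(counts.get(aa, 0), 0.5) for aa in STANDARD_AA}
        total = sum(adjusted.values())
        freq[o] = {aa: c / total for aa, c in adjusted.items()}
    return PositionalBackground(freq=freq, source="tested_peptides")


def binder_enrichment(
    selection: BinderSelection,
    all_summaries: pd.DataFrame,
    alpha: float = 0.05,
    offsets: Sequence[int] = CORE_OFFSETS,
) -> EnrichmentTable:
    """Residue enrichment of the strong binders relative to all tested peptides.

    Foreground = cores of the selected peptides; background = positional
    residue composition of every tested core. Offsets -3..+3 excluding the
    citrulline itself.
    """
    if selection.n_selected == 0:
        raise ValueError("empty binder selection")
    by_id = all_summaries.set_index("peptide_id")["core"]
    fg_cores = [by_id[pid] for pid in selection.peptide_ids]
    background = positional_background_from_cores(by_id.tolist(), offsets)
    windows = _cores_to_windows(fg_cores, offsets)
    return compute_enrichment(windows, background, alpha=alpha)
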