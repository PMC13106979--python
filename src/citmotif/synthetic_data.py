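"""Synthetic inputs with known ground truth for every pipeline stage.

Provides a background proteome generator, motif-planted citrullination
sites (so motif recovery can be checked against the planted spec), and a
simulated peptide-microarray readout driven by a position-additive antibody
affinity model with multiplicative log-normal noise — the standard noise
model for fluorescence intensities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .array_design import (
    ArrayDesign,
    CORE_CENTER,
    CORE_OFFSETS,
    build_motif_set,
    build_non_motif_set,
    layout_array,
    nonmotif_complements,
)
from .immunogen_design import (
    PositionWeightSpec,
    immunization_pool_spec,
    largest_remainder_percents,
)
from .residues import STANDARD_AA


# ---------------------------------------------------------------------------
# proteome generation


def generate_proteome(
    n_proteins: int,
    mean_length: int = 400,
    residue_freqs: Mapping[str, float] | None = None,
    seed: int = 0,
    min_length: int = 50,
) -> dict[str, str]:
    """Seeded random proteome; residue composition converges to residue_freqs.

    Lengths are Poisson(mean_length), floored at ``min_length``. The default
    composition is uniform over the 20 standard amino acids.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    aas = np.array(list(STANDARD_AA))
    if residue_freqs is None:
        probs = np.full(20, 0.05)
    else:
        probs = np.array([residue_freqs.get(aa, 0.0) for aa in STANDARD_AA], dtype=float)
        probs = probs / probs.sum()
    proteome = {}
    for i in range(n_proteins):
        length = max(min_length, int(rng.poisson(mean_length)))
        proteome[f"SYN{i:05d}"] = "".join(rng.choice(aas, size=length, p=probs))
    return proteome


def write_fasta(proteome: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for pid, seq in proteome.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return path


# ---------------------------------------------------------------------------
# motif-planted sites


def plant_sites(
    proteome: Mapping[str, str],
    spec: PositionWeightSpec,
    n_sites: int,
    seed: int = 0,
    W: int = 5,
) -> tuple[dict[str, str], list[tuple[str, int, str]]]:
    """Plant citrullination sites whose flanks follow the spec's weights.

    Proteins are partitioned into disjoint blocks of width 2W+1; ``n_sites``
    blocks are chosen at random, the block center is rewritten to R and the
    flanking positions at the spec's offsets are redrawn from the spec's
    percent weights. Disjoint blocks guarantee planted windows never overlap.
    Returns the edited proteome and the ground-truth site list
    (protein_id, 1-based position, "R").
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    block = 2 * W + 1
    slots: list[tuple[str, int]] = []  # (protein_id, 1-based site position)
    for pid, seq in proteome.items():
        for b in range(len(seq) // block):
            slots.append((pid, b * block + W + 1))
    if n_sites > len(slots):
        raise ValueError(f"proteome hosts only {len(slots)} sites, requested {n_sites}")

    rng = np.random.default_rng(seed)
    edited = {pid: list(seq) for pid, seq in proteome.items()}
    chosen = rng.choice(len(slots), size=n_sites, replace=False) if n_sites else []
    sites: list[tuple[str, int, str]] = []
    for idx in sorted(int(i) for i in np.atleast_1d(chosen)):
        pid, pos = slots[idx]
        seq = edited[pid]
        seq[pos - 1] = "R"
        for offset in spec.offsets:
            residues = np.array(spec.residues(offset))
            probs = np.array(spec.percents(offset), dtype=float) / 100.0
            seq[pos - 1 + offset] = str(rng.choice(residues, p=probs))
        sites.append((pid, pos, "R"))
    return {pid: "".join(seq) for pid, seq in edited.items()}, sites


def write_sites(sites: Sequence[tuple[str, int, str]], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(sites, columns=["protein_id", "position", "residue"]).to_csv(
        path, sep="\t", index=False
    )
    return path


# ---------------------------------------------------------------------------
# antibody model and array simulation


@dataclass(frozen=True)
class AntibodyModel:
    """Position-additive log-affinity model of antibody binding.

    A peptide spot's expected signal is
    ``base_signal * exp(sum_o weights[o, residue_o])``; replicate noise is
    multiplicative log-normal with sigma ``noise_sigma``. Blank spots are
    log-normal with parameters (blank_mu, blank_sigma) on the log scale;
    synthesis-control spots sit at a fixed level.
    """

    weights: dict[tuple[int, str], float]
    base_signal: float = 1000.0
    noise_sigma: float = 0.3
    blank_mu: float = math.log(50.0)
    blank_sigma: float = 0.5
    control_signal: float = 800.0

    def __post_init__(self) -> None:
        if self.base_signal <= 0:
            raise ValueError("base_signal must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def log_affinity(self, core: str) -> float:
        return sum(
            self.weights.get((o, core[CORE_CENTER + o]), 0.0) for o in CORE_OFFSETS
        )


def motif_aligned_model(
    spec: PositionWeightSpec, scale: float = 2.0, **kwargs
) -> AntibodyModel:
    """Antibody whose per-position preferences mirror the spec's weights.

    weight(offset, residue) = scale * percent / 100 at the core offsets; all
    other residues get 0 (no preference).
    """
    weights = {
        (o, r): scale * p / 100.0
        for o in spec.offsets
        if o in CORE_OFFSETS
        for r, p in spec.residues_at[o]
    }
    return AntibodyModel(weights=weights, **kwargs)


def simulate_array(
    design: ArrayDesign, model: AntibodyModel, seed: int = 0
) -> pd.DataFrame:
    """Simulate per-spot F635 fluorescence for a designed array.

    Deterministic given the seed; with ``noise_sigma = 0`` the peptide spot
    signal is an exact function of design and model.
    """
    rng = np.random.default_rng(seed)
    mapping = design.mapping()
    affinity_by_core = {
        core: model.log_affinity(core) for core in design.peptides["core"]
    }
    signal = np.empty(len(mapping))
    is_pep = (mapping["kind"] == "peptide").to_numpy()
    is_ctrl = (mapping["kind"] == "control").to_numpy()
    is_blank = (mapping["kind"] == "blank").to_numpy()

    core_aff = mapping.loc[is_pep, "core"].map(affinity_by_core).to_numpy(dtype=float)
    noise = (
        rng.normal(0.0, model.noise_sigma, size=is_pep.sum())
        if model.noise_sigma > 0
        else np.zeros(is_pep.sum())
    )
    signal[is_pep] = model.base_signal * np.exp(core_aff + noise)
    signal[is_ctrl] = model.control_signal
    signal[is_blank] = np.exp(
        rng.normal(model.blank_mu, model.blank_sigma, size=is_blank.sum())
    )

    return pd.DataFrame(
        {
            "spot_index": mapping["spot_index"],
            "peptide_id": mapping["peptide_id"],
            "kind": mapping["kind"],
            "f635_mean": signal,
            "flag": 0,
        }
    )


def write_spot_table(df: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> Path:
    """Write a simulated spot table as plain TSV or a GPR-style text file."""
    path = Path(path)
    if dialect == "tsv":
        df.to_csv(path, sep="\t", index=False)
        return path
    if dialect == "gpr":
        ncols = int(math.ceil(math.sqrt(len(df))))
        with open(path, "w") as fh:
            fh.write("ATF\t1.0\n2\t8\n")
            fh.write('"Type=GenePix Results 3"\n')
            fh.write('"Wavelengths=635"\n')
            fh.write(
                "\t".join(
                    ["Block", "Column", "Row", "Index", "Name", "ID", "F635 Mean", "Flags"]
                )
                + "\n"
            )
            for i, row in enumerate(df.itertuples(index=False)):
                fh.write(
                    "\t".join(
                        [
                            "1",
                            str(i % ncols + 1),
                            str(i // ncols + 1),
                            str(int(row.spot_index)),
                            str(row.peptide_id),
                            str(row.peptide_id),
                            f"{row.f635_mean:.2f}",
                            str(int(row.flag)),
                        ]
                    )
                    + "\n"
                )
        return path
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# fixture bundles


def reduced_spec(spec: PositionWeightSpec, k: int = 2) -> PositionWeightSpec:
    """Keep the ``k`` highest-weight residues per offset, renormalized to 100."""
    residues_at = {}
    for o in spec.offsets:
        pairs = sorted(spec.residues_at[o], key=lambda rp: (-rp[1], rp[0]))[:k]
        percents = largest_remainder_percents([p for _, p in pairs])
        residues_at[o] = tuple((r, p) for (r, _), p in zip(pairs, percents))
    return PositionWeightSpec(residues_at)


def make_fixture_bundle(out_dir: str | Path, scale: str = "tiny", seed: int = 0) -> dict:
    """Write a complete synthetic input bundle and its ground-truth manifest.

    ``paper`` scale reproduces the study's design cardinalities (20,480 motif
    + 44,000 non-motif peptides in triplicate, 2,495 controls, 2,500 blanks);
    ``tiny`` is a reduced-residue-set version that runs in seconds. Files:
    proteome.fasta, sites.tsv, design/, signals.tsv, signals.gpr, truth.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=5)]
    pool = immunization_pool_spec()

    if scale == "tiny":
        spec = reduced_spec(pool, k=2)
        n_proteins, mean_length, n_sites = 60, 400, 150
        n_nonmotif, n_controls, n_blanks = 500, 50, 50
    elif scale == "paper":
        # the proteome must dwarf the planted residues, as a real proteome
        # does, or planting itself would skew the background composition
        spec = pool
        n_proteins, mean_length, n_sites = 2000, 600, 5000
        n_nonmotif, n_controls, n_blanks = 44000, 2495, 2500
    else:
        raise ValueError(f"unknown scale {scale!r}")

    proteome = generate_proteome(n_proteins, mean_length=mean_length, seed=sub[0])
    planted, sites = plant_sites(proteome, spec, n_sites, seed=sub[1])
    write_fasta(planted, out_dir / "proteome.fasta")
    write_sites(sites, out_dir / "sites.tsv")

    motif_set = build_motif_set(spec)
    non_motif_set = build_non_motif_set(nonmotif_complements(spec), n_nonmotif, seed=sub[2])
    design = layout_array(
        motif_set,
        non_motif_set,
        replicates=3,
        n_controls=n_controls,
        n_blanks=n_blanks,
        seed=sub[3],
    )
    design.write(out_dir / "design")

    model = motif_aligned_model(spec)
    signals = simulate_array(design, model, seed=sub[4])
    write_spot_table(signals, out_dir / "signals.tsv", dialect="tsv")
    write_spot_table(signals, out_dir / "signals.gpr", dialect="gpr")

    manifest = {
        "scale": scale,
        "seed": seed,
        "subseeds": {
            "proteome": sub[0],
            "sites": sub[1],
            "non_motif_set": sub[2],
            "layout": sub[3],
            "signals": sub[4],
        },
        "n_proteins": n_proteins,
        "n_sites": n_sites,
        "n_motif_peptides": len(motif_set),
        "n_non_motif_peptides": len(non_motif_set),
        "n_spots": design.n_spots,
        "planted_spec": {
            str(o): dict(spec.residues_at[o]) for o in spec.offsets
        },
        "antibody_weights": {f"{o}:{r}": w for (o, r), w in model.weights.items()},
        "base_signal": model.base_signal,
        "noise_sigma": model.noise_sigma,
    }
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
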