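"""Window extraction, background models, and the binomial enrichment statistic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from citmotif.motif_enrichment import (
    BackgroundModel,
    SiteWindow,
    background_from_proteome,
    background_from_windows,
    binomial_tail,
    compute_enrichment,
    extract_windows,
    read_proteome,
    select_motif_residues,
)
from citmotif.residues import PAD, STANDARD_AA


def pmf_sum_tail(k: int, n: int, q: float, tail: str) -> float:
    """Independent oracle: explicit binomial pmf summation via math.comb."""
    js = range(k, n + 1) if tail == "over" else range(0, k + 1)
    return sum(math.comb(n, j) * q**j * (1 - q) ** (n - j) for j in js)


# ---------------------------------------------------------------------------
# proteome / window plumbing


def test_read_proteome_parses_ids_and_sequences(tmp_path):
    path = tmp_path / "p.fasta"
    path.write_text(">P1 some description\nACDEF\n>P2\nGHIKL\nMNP\n")
    proteome = read_proteome(path)
    assert proteome == {"P1": "ACDEF", "P2": "GHIKLMNP"}


@pytest.mark.parametrize(
    "content", [">P1\nAC\n>P1\nGG\n", "", "not fasta at all\n"]
)
def test_read_proteome_rejects_bad_input(tmp_path, content):
    path = tmp_path / "bad.fasta"
    path.write_text(content)
    with pytest.raises(ValueError):
        read_proteome(path)


def test_extract_windows_flanks_and_padding():
    proteome = {"P1": "GSRYE", "P2": "RAAAA"}
    ext = extract_windows(proteome, [("P1", 3, "R"), ("P2", 1, "R")], W=2)
    w1, w2 = ext.windows
    assert w1.offsets == (-2, -1, 1, 2)
    assert w1.residues == ("G", "S", "Y", "E")
    assert w1.central_residue == "R"
    assert w2.residues == (PAD, PAD, "A", "A")


def test_extract_windows_counts_mismatches_without_dropping_the_rest():
    proteome = {"P1": "GSRYE"}
    ext = extract_windows(proteome, [("P1", 3, "R"), ("P1", 2, "R")], W=1)
    assert len(ext.windows) == 1
    assert ext.n_mismatched == 1
    assert ext.mismatched_sites[0] == ("P1", 2, "R", "S")


def test_extract_windows_unknown_protein_is_fatal():
    with pytest.raises(KeyError):
        extract_windows({"P1": "GSRYE"}, [("NOPE", 1, "G")], W=1)


# ---------------------------------------------------------------------------
# backgrounds


def test_background_uniform_proteome():
    bg = background_from_proteome({"P1": STANDARD_AA})
    assert all(abs(q - 0.05) < 1e-12 for q in bg.residue_freq.values())


def test_background_matches_hand_tally():
    # P1 covers all 20 once; P2 adds 2xA and 1xC -> A:3, C:2, rest 1 (total 23)
    bg = background_from_proteome({"P1": STANDARD_AA, "P2": "AAC"})
    assert bg.residue_counts["A"] == 3
    assert bg.residue_freq["A"] == pytest.approx(3 / 23)
    assert bg.residue_freq["C"] == pytest.approx(2 / 23)
    assert bg.residue_freq["W"] == pytest.approx(1 / 23)


def test_background_floors_absent_residues():
    bg = background_from_proteome({"P1": "AAAA"})
    assert all(q > 0 for q in bg.residue_freq.values())
    assert sum(bg.residue_freq.values()) == pytest.approx(1.0)
    assert bg.residue_freq["A"] == pytest.approx(4 / (4 + 19 * 0.5))


def test_background_excludes_nonstandard_letters():
    bg = background_from_proteome({"P1": STANDARD_AA + "XXXB"})
    assert bg.residue_counts["A"] == 1
    assert sum(bg.residue_counts.values()) == 20


def test_background_requires_standard_residues():
    with pytest.raises(ValueError):
        background_from_proteome({"P1": "XXXX"})


def test_window_empirical_background_counts_flanks_only():
    ext = extract_windows({"P1": "GSRYE"}, [("P1", 3, "R")], W=2)
    bg = background_from_windows(ext.windows)
    # flanks G,S,Y,E once each; central R never counted
    assert bg.residue_counts["G"] == 1
    assert bg.residue_counts["R"] == 0


# ---------------------------------------------------------------------------
# binomial tails


def test_binomial_tail_closed_forms():
    assert binomial_tail(0, 5, 0.3, "over") == pytest.approx(1.0)
    assert binomial_tail(5, 5, 0.5, "over") == pytest.approx(0.5**5)
    assert binomial_tail(0, 5, 0.5, "under") == pytest.approx(0.5**5)


def test_binomial_tail_matches_pmf_summation_grid():
    qs = [0.01, 0.05, 0.1, 0.3, 0.5, 0.7, 0.95]
    for n in range(1, 51, 7):
        for k in range(0, n + 1):
            for q in qs:
                for tail in ("over", "under"):
                    expected = pmf_sum_tail(k, n, q, tail)
                    got = binomial_tail(k, n, q, tail)
                    assert got == pytest.approx(expected, rel=1e-9)


@pytest.mark.parametrize("k,n,q", [(-1, 5, 0.5), (6, 5, 0.5), (2, 5, 0.0), (2, 5, 1.0)])
def test_binomial_tail_rejects_out_of_range(k, n, q):
    with pytest.raises(ValueError):
        binomial_tail(k, n, q)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    n=st.integers(1, 40),
    q=st.floats(0.01, 0.99),
    data=st.data(),
)
def test_binomial_tail_monotone_in_k(n, q, data):
    k = data.draw(st.integers(1, n))
    assert binomial_tail(k, n, q, "over") <= binomial_tail(k - 1, n, q, "over")
    assert binomial_tail(k, n, q, "under") >= binomial_tail(k - 1, n, q, "under")


# ---------------------------------------------------------------------------
# enrichment tables


def _windows_from_columns(columns: dict[int, list[str]]) -> list[SiteWindow]:
    offsets = tuple(sorted(columns))
    n = len(next(iter(columns.values())))
    return [
        SiteWindow(
            protein_id=f"w{i}",
            site_pos=10,
            central_residue="R",
            offsets=offsets,
            residues=tuple(columns[o][i] for o in offsets),
        )
        for i in range(n)
    ]


def uniform_background() -> BackgroundModel:
    return BackgroundModel(
        residue_freq={aa: 0.05 for aa in STANDARD_AA},
        source="proteome_global",
        residue_counts={aa: 1 for aa in STANDARD_AA},
    )


def test_compute_enrichment_matches_pmf_oracle():
    # 8 windows, G at -1 in 6 of them, q_G = 0.07
    freqs = {aa: (0.07 if aa == "G" else 0.93 / 19) for aa in STANDARD_AA}
    bg = BackgroundModel(freqs, "proteome_global", {aa: 1 for aa in STANDARD_AA})
    cols = {-1: list("GGGGGGAS"), 1: list("AAAAAAAA")}
    table = compute_enrichment(_windows_from_columns(cols), bg, alpha=0.05)
    cell = table.cell(-1, "G")
    expected = pmf_sum_tail(6, 8, 0.07, "over")
    assert cell.p_over == pytest.approx(expected, rel=1e-9)
    assert table.n_tests == 40  # 20 residues x 2 scored offsets
    assert bool(cell.significant) == (expected < 0.05 / 40)


def test_enrichment_count_conservation():
    rng = np.random.default_rng(3)
    cols = {
        o: list(rng.choice(list(STANDARD_AA), size=50)) for o in (-2, -1, 1, 2)
    }
    table = compute_enrichment(_windows_from_columns(cols), uniform_background())
    for o, sub in table.table.groupby("offset"):
        assert sub["k"].sum() == sub["n"].iloc[0] == 50
    # over and under tails share the point mass at k
    assert (table.table.p_over + table.table.p_under >= 1 - 1e-12).all()


def test_enrichment_single_window():
    table = compute_enrichment(
        _windows_from_columns({-1: ["G"], 1: ["A"]}), uniform_background()
    )
    assert set(table.table["k"].unique()) <= {0, 1}
    assert (table.table.groupby("offset")["k"].sum() == 1).all()


def test_enrichment_all_padded_offset_reports_n_zero():
    w = SiteWindow("p", 1, "R", (-1, 1), (PAD, "A"))
    table = compute_enrichment([w], uniform_background())
    sub = table.table[table.table.offset == -1]
    assert (sub["n"] == 0).all()
    assert not sub["significant"].any()
    assert table.n_tests == 20  # only the +1 offset is scored


def test_select_motif_residues_weights_by_largest_remainder():
    # only G (k=6) and S (k=2) significant at -1 -> 75 / 25
    # q = 0.002 makes even k=2 of 8 clear the 0.05/40 Bonferroni threshold
    freqs = {aa: (0.002 if aa in "GS" else 0.996 / 18) for aa in STANDARD_AA}
    bg = BackgroundModel(freqs, "proteome_global", {aa: 1 for aa in STANDARD_AA})
    cols = {-1: list("GGGGGGSS"), 1: list("AAAAAAAA")}
    table = compute_enrichment(_windows_from_columns(cols), bg, alpha=0.05)
    spec = select_motif_residues(table)
    assert dict(spec.residues_at[-1]) == {"G": 75, "S": 25}


def test_select_motif_residues_empty_when_nothing_significant():
    cols = {-1: list("GA"), 1: list("ST")}
    table = compute_enrichment(_windows_from_columns(cols), uniform_background())
    spec = select_motif_residues(table)
    assert spec.residues_at == {}


def test_select_rejects_mismatched_alpha():
    cols = {-1: list("GA"), 1: list("ST")}
    table = compute_enrichment(_windows_from_columns(cols), uniform_background())
    with pytest.raises(ValueError):
        select_motif_residues(table, alpha=0.01)
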