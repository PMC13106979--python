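# Methods

## The enrichment statistic

For each flanking offset *p* (offset 0 is the modified residue itself and is
never tested) and each of the 20 standard amino acids *r*, we count the
foreground occurrences *k* among the *n_p* windows with a standard residue at
*p*, and compare them with a background probability *q* by exact binomial
tails: p_over = P(X ≥ k) and p_under = P(X ≤ k) for X ~ Binomial(n_p, q)
(computed with scipy's regularized incomplete beta, which is exact to
floating-point precision; the suite verifies agreement with explicit pmf
summation to < 1e-9 relative error for n ≤ 50). The exported score is the
signed −log₁₀ of the smaller tail: positive for over-representation
(−log₁₀ p_over), negative for under-representation (log₁₀ p_under). When the
tails tie, the cell is reported on the over-representation side. Tails are
floored at 1e-300 before taking logs so scores stay finite.

Multiple testing uses Bonferroni with n_tests = 20 residues × the number of
scored offsets (offsets where every window is padded are reported with
n_p = 0 and excluded from the denominator). Each one-sided tail is compared
separately to α / n_tests; this matches per-residue-per-position testing as
done by pLogo-style tools. Pad tokens ("-") and non-standard letters are
excluded from both *k* and *n_p*, which preserves the conservation law
Σ_r k(p, r) = n_p at every offset.

Two background models are available. The default, `proteome_global`, uses the
position-independent residue frequencies of the supplied proteome — the
conventional choice when asking "which residues are enriched relative to the
proteome". The alternative `window_empirical` uses the composition of the
extracted windows themselves. Zero-count residues are floored with a 0.5
pseudocount before normalization so every *q* lies strictly in (0, 1); this
only matters for degenerate toy proteomes, where the floor substitutes for an
otherwise undefined test.

Motif selection keeps, per offset, the significantly over-represented
residues and renormalizes their observed foreground frequencies to integer
percents with largest-remainder rounding (floors plus distribution of the
shortfall by fractional remainder, first-listed winning ties), so each
offset's percents sum to exactly 100 — the convention used by the packaged
immunization-pool table. Offsets without significant residues are omitted;
an empty specification is a valid outcome.

## Immunogen pool combinatorics

A position-weight specification lists, per offset, admitted residues with
integer percent weights summing to 100. The pool size is the exact product
of per-offset set sizes (arbitrary-precision integers). Enumeration is
offset-major with spec-listed residue order, so it is deterministic and
duplicate-free; sampling draws residues independently per offset with
probability percent/100 and is seeded. Sampling is with replacement by
default — a synthesis pool is a mixture, not a set — with a distinct-only
mode via rejection. The packaged specification spans offsets −4…−1 and
+1…+5 with residue-set sizes (4,4,4,4,4,4,4,5,6), giving 4⁷ × 5 × 6 =
491,520 unique 10-mers.

Citrulline is rendered in exports as "R" plus a 1-based annotation
("cit@5"), or inline as "R[cit]" for single-column formats; both round-trip
losslessly. A bare unannotated R is never written for a citrulline.

## Array design

The motif core set is the Cartesian product of the specification's residue
sets at −3…+3 with position +1 opened to all 20 residues (alphabetical
order), yielding 20,480 cores for the packaged spec. The non-motif set draws
uniformly from each position's complement (the 20 standard residues minus
the motif residues; at +1, minus the motif-enriched residues G, S, A, D),
with rejection sampling enforcing uniqueness — 44,000 cores from a 16⁶ ≈
16.8M space, disjoint from the motif set by construction since the residue
alphabets differ at every position. A `global_exclusions` option removes
residues (e.g. C and V, as is common to avoid disulfides and excessive
hydrophobicity) from all complements. Cores are flanked with SG (N-terminal)
and SGS (C-terminal) linkers for synthesis. The layout is a seeded random
permutation of all replicate, control (EDKFVRYVD) and blank spots; geometry
is abstract (a 1-D spot index), with a near-square block/row/col grid applied
only when writing the GAL-like table, since no physical grid is modeled.

## Array analysis

Spot tables are parsed by header keys only ("F635 Mean", optional "Flags",
"ID"/"Name"); identities come from the design mapping via the spot index.
Per-peptide signal is the arithmetic mean of valid (flag = 0) replicates;
peptides with no valid replicate are excluded and counted. No normalization
is applied by default — raw F635 means are the readout. Strong binders are
the top quantile (default 0.25) of mean signal across *all* tested peptides
regardless of group: exactly floor(q·n) peptides, ranked by signal
descending with boundary ties broken by ascending peptide id so the
selection is deterministic.

Binder motif reconstruction reuses the enrichment machinery with foreground
= selected cores and a *positional* background: the per-offset residue
frequencies of every tested core (0.5-pseudocounted). A proteome background
would be wrong here — the tested library is heavily non-uniform by design,
and the question is what the antibody prefers *within what it was shown*.

## The synthetic-data generator

`generate_proteome` draws i.i.d. residues (default uniform over the 20
standard amino acids) with Poisson-distributed lengths. `plant_sites`
partitions proteins into disjoint blocks of width 2W+1, picks the requested
number of blocks at random, sets each block center to R and redraws the
flanking residues at the specification's offsets from its percent weights;
disjoint blocks guarantee planted windows never overlap and the ground-truth
site list is exact. The default recovery condition uses 2,000 proteins of
mean length 600 (~1.2M residues) for 5,000 planted sites: the proteome must
dwarf the planted residues, as a real proteome does, because planting
rewrites ~11 residues per site and would otherwise shift the global
background composition enough to create spurious enrichment at unplanted
offsets.

Array fluorescence follows a position-additive log-affinity model: a peptide
spot's signal is base_signal × exp(Σ_p w(p, residue_p)) × exp(ε) with
ε ~ Normal(0, σ²) per replicate — multiplicative log-normal noise, the
standard model for fluorescence intensities, with σ = 0.3 by default (~30%
replicate CV, typical of spotted arrays). Blank spots are log-normal
(μ = log 50, σ = 0.5 on the log scale) and synthesis controls sit at a fixed
level. With σ = 0 the simulation is an exact, bitwise-reproducible function
of design and model. The bundled "motif-aligned" antibody sets
w(p, r) = 2 × percent/100 for the specification's residues at core offsets,
zero elsewhere.

What the generator does *not* emulate: spatial gradients and scanner
saturation, sequence-composition effects on synthesis yield, cross-reactive
binding modes, and the correlated noise structure of real scans. Passing
tests therefore demonstrate correctness of the computational procedure under
a known generative model, not performance on real array data.

Fixture bundles come in two scales: `tiny` (a 2-residue-per-offset reduction
of the packaged spec; ~3.5k spots; seconds) and `paper` (the full design
cardinalities: 20,480 + 44,000 peptides in triplicate, 2,495 controls,
2,500 blanks, 198,435 spots). All randomness flows from one seed per bundle;
derived sub-seeds are recorded in the truth manifest.

## Modification levels

A peptide counts as modified if it carries at least one modification of the
queried type (multiple sites count once). Both denominators are reported:
peptides containing the target residue, and all peptides — by count and by
summed intensity. When no peptide contains the target residue the
target-based percentages are undefined (None), not zero. Peptide entries are
counted as unique table rows; if a search engine exports PSM-level rows, the
caller should collapse them first. Mass deltas are recomputed from
monoisotopic atomic masses (H 1.0078250, C 12, N 14.0030740, O 15.9949146):
citrullination/deamidation = +O −N −H = +0.98402 Da (the two are isobaric,
which is exactly why MS localization of citrullination is hard), and
carbamylation = +H +C +N +O = +43.00581 Da.

## Numerical and design choices

* Binomial tails in scipy rather than naive summation: exact and stable for
  large n; the naive summation survives as the test oracle.
* Selection quantile rule floor(q·n) with deterministic tie-breaking: the
  top-quartile definition leaves rounding and ties unspecified, so the
  package fixes one reproducible convention.
* Published strong-binder counts from the original array experiments
  (7,652 and 8,351) are not a strict quartile of 64,480 peptides (which is
  16,120); they evidently reflect an additional unpublished filter. The
  package implements the documented procedure and reports its own counts.
* Known limitations: no inter-array normalization (each clone's array is
  analyzed alone); no modeling of the 532 nm artifact channel; enrichment
  assumes windows are independent observations (overlapping sites in real
  data mildly violate this).
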