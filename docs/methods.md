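# Methods

## Alignment objective

The aligner solves semi-global spliced alignment of a protein query
against a genomic segment.  Paths are built from five move families:

* **diagonal (D)** — one query residue against one in-frame codon, scored
  by BLOSUM62 over the translated codon.  Stop codons are not forbidden:
  they score a large negative constant (default −50), which permits
  pseudogene-like alignments while strongly disfavouring them.  Codons
  containing `N` score as `X`.
* **vertical (V)** — an unpaired query residue; affine cost `v + u` to
  open, `u` to extend (defaults v = 8, u = 2 matrix units).
* **horizontal (H)** — an unpaired in-frame codon, same affine structure
  with one codon as the unit.  Horizontal gaps are whole codons;
  frameshift-tolerant 1–2 nt gaps are out of scope.
* **intron (I0/I1/I2)** — opens at a potential donor from a D or H cell at
  codon phase 0, 1 or 2 (the phase counts nucleotides of the current
  codon already emitted), extends free of per-nucleotide charge, and
  closes at a compatible potential acceptor, paying donor signal +
  acceptor signal − intron penalty.  A phase-p intron leaves p
  nucleotides before the donor; the codon is completed by 3−p
  nucleotides after the acceptor and scored as one substitution
  ("bridged codon").
* **HI** — the rare case of a deletion in the query striding across an
  intron: opened from an H cell, closed back into H on the same row with
  no second gap-open charge.

Semi-global boundary conditions: genomic prefix/suffix free (row 0 of the
D layer is 0 at every column), query terminal gaps charged through the V
layer.  A configurable minimum report score (CLI default 35, library
default 0) converts weak optima into a "no alignment" result.

A potential splice site is a dinucleotide that matches a listed rule with
signal score above a threshold.  Defaults: donors GT 0, GC −6, AT −8;
acceptors AG 0, AC −2; threshold −10.  AT donors pair only with AC
acceptors.  These untrained scores rank the three canonical classes in
their observed frequency order; no position-weight matrices, branch
points or polypyrimidine tracts are modelled.

## Intron penalty modes

* **FULL**: `round(α + β·ln ℓ)` clamped at 0, defaults α = −15, β = 6,
  giving ≈5 at the 30 nt minimum and ≈40 at 10 kb — a few codon
  identities per e-fold of length.  An empirical stepwise table can
  override the log-affine form.
* **COARSE** (grain G, default 1024 nt): FULL evaluated at the geometric
  midpoint of the bin `[kG, (k+1)G)` — the geometric midpoint minimises
  the multiplicative error of the log term, and the deviation from FULL
  within bin k is bounded by `β·ln((k+1)/k)` plus rounding.
* **CONSTANT**: flat IP0 (default 20) regardless of length.

Introns shorter than `min_length` (default 30 nt) are forbidden.  Mode
aliases a0/a1 both mean FULL (they are required to produce identical
results), a2 COARSE, a3 CONSTANT.

All penalties are rounded to integer matrix units.  Integer scoring is a
deliberate numerical choice: the score audit (component sum equals DP
score) is exact by construction, and deterministic tie-breaking is
well-defined.  Tie order: diagonal-from-D > diagonal-from-H >
diagonal-from-V > intron closes (lower phase first; among tied donors the
shorter intron); end cells prefer D > H > V, then the smaller column.

## Exact recurrence in O(1) amortised per cell

Length-dependent intron penalties obstruct the classic single running
maximum over pending donors.  The resolution here: per (phase,
acceptor-class, partial-codon) the pending donors form a Pareto list — a
donor is dominated by any later donor with an equal-or-better entry
score, because every penalty mode is non-decreasing in intron length.
Closes scan only the Pareto survivors (a constant-factor list in
practice; exactly one element in CONSTANT mode), keeping the recurrence
exact in all three modes.  Phase-1/2 pendings are keyed by their 1–2
leading nucleotides so the bridged codon is scored exactly, never
approximated.

## Linear-space traceback

The forward pass stores a two-byte packed move per cell only inside
sub-rectangles.  Crossing coordinates are recorded at the *arrival* cell
on each intermediate row — the cell reached by the diagonal or vertical
move entering the row — which is why two link layers (d = 2, the affine
case) suffice: `VL[c][0][j]` and `VL[c][1][j]` hold the crossing of the
best path to the D- and V-layer cells.  After each intermediate row the
links refresh: D and V cells to their own identity, H cells to their gap
origin (the HL semantics), so horizontal travel along a row transmits the
row's true arrival cell.  An intron close departing an intermediate row
transmits a packed jump record (donor, phase, base layer, landing); the
reconstruction then re-fills only a one-row strip up to the donor plus
the rectangle above the landing — the intron interior is never re-filled,
which the test suite checks by counting recalculated cells.

Memory model: `M(k, m, n) = 16nk + 2mn(k+1)⁻²` bytes (4-byte link
entries, 2-byte traceback cells), continuous minimiser
`k̂ = (m/4)^⅓ − 1`; the integer k is whichever of floor/ceil gives the
smaller M (n cancels), floored at 1.  Intermediate rows are
`⌊c·m/(k+1)⌋`; floor division is our choice where rounding is
unspecified.  An instrumented counter (not OS memory) tracks traceback
and link allocations and is asserted against `M + 16kn` on test
instances.

The hybrid strategy under the budget `V_max` (default 16 MiB,
configurable): full-matrix when `2mn ≤ V_max`; MIUDH with k̂ when
`M(k̂, m, n) < V_max`; otherwise a recursive single-intermediate split at
row m/2 whose subproblems re-enter the decision.  Because both kernels
apply the identical tie order, every branch returns the identical gene
model, not merely the same score — asserted move-for-move across the test
battery.

## Banded variant

The banded mode restricts each row's dense recurrence to a window of
`band_width` codons around a centre that starts at the segment origin and
re-anchors to the previous row's best cell; intron closes are evaluated
at any landing column, so introns bypass the band by jump moves and the
window re-centres across them.  This concretisation equals the
full-matrix optimum whenever the unrestricted optimal path stays inside
the moving window; a path touching a window edge sets a truncation flag
on the result.  It is intended for the side-by-side regime where the
genic segment is already known.

## Mapping heuristics

Candidate loci come from a three-level HSP search over six-frame reduced
translations.  Level 3 uses alphabet size 10, k-mer weight 4 and spaced
seed `11011`; level 1 runs genome-wide with the weight-3 seed `1101` on a
12-letter alphabet; level 2 is the intermediate refinement.  The
groupings (e.g. {LVIM, C, A, G, ST, P, FYW, EDNQ, KR, H} at size 10) are
hydrophobicity/charge clusters — a documented free choice; only the sizes
are structural.  Diagonals `j − 3i` are bucketed with a per-level shift
tolerance, diagonals holding more hits than the level minimum are
extended with the ungapped X-drop algorithm (default X = 20), and HSPs
chain greedily under colinearity with genomic gaps up to the maximum
intron length; a mild cost of one matrix unit per 2 kb of genomic gap
keeps isolated noise HSPs from inflating windows.  Chained windows carry
a margin (default 10 kb genome-wide, 500 nt after refinement) into the
aligner.  Minus-strand loci are aligned against the reverse-complemented
window and coordinates are flipped back on output, keeping the DP engine
strand-agnostic.

## Synthetic data

The generator emulates what the aligner must handle: multi-exon genes
(1–8 exons, log-normal exon lengths, median 140 nt), log-normal intron
lengths (median 300 nt, minimum 30), canonical boundary classes at
frequencies 0.98 / 0.015 / 0.005 (GT..AG / GC..AG / AT..AC), i.i.d.
intergenic background at configurable GC (default 0.45), uniform
synonymous codon usage, and queries diverged to a target percent identity
with BLOSUM-biased substitutions (`P(b|a) ∝ 2^(s(a,b)/2)`) and 1–3
residue indels at a configurable per-residue rate (default 0.01).
Realised pid is measured by exact global protein re-alignment.  In
multi-intron batteries at least one phase-1 and one phase-2 intron are
forced so bridged-codon scoring is always exercised.

Two interior bases adjacent to each junction are constrained (no second
donor dinucleotide immediately after the donor; no acceptor dinucleotide
one base early) so that no equal-length junction slide preserves both the
splice classes and the translation — combined with the strictly positive
intron penalty this makes the true structure the unique optimum for
native queries, and noise-free recovery a deterministic expectation.
What the generator does *not* model — codon bias, branch points,
isoforms, paralogs, repeats, assembly gaps — bounds what passing tests
say about real genomes: they validate the algorithmic machinery, not
biological signal strength.

## Problem sizes used in the checked examples

The test battery uses queries up to ~300 residues on segments up to a few
kilobases for the oracle-equivalence and algorithm-identity sweeps, 50
genes for noise-free recovery, 40 genes per divergence level at target
pid {95, 85, 75, 65, 55}, and 20 genes on a ~1.1 Mb background for
mapping sensitivity — sizes at which every run is exact and repeatable
with fixed seeds.

## Known limitations

* No frameshifts, DNA/cDNA queries, or profile queries.
* Translation initiation/termination signals are not modelled beyond the
  first/last aligned codon.
* Splice signals are rule-plus-constant scores, not trained models; real
  genomes need species-specific parameter files.
* The banded mode's adaptive centre is a heuristic; its optimality
  guarantee is conditional on the path staying in the window.
* The Pareto pending lists are worst-case linear per close (adversarial
  monotone donor scores), though constant-factor on all tested data.
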