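# intronalign

Codon-aware spliced alignment of protein queries onto eukaryotic genomic
DNA, with linear-space traceback.

Gene annotation pipelines routinely align homologous proteins from other
species against a newly assembled genome: the protein survives evolutionary
change far better than the nucleotide sequence, but the genomic copy of the
gene is interrupted by introns, so the aligner must simultaneously translate
the genome, place gaps, and decide where introns start (donor, typically
`GT`) and end (acceptor, typically `AG`) — including introns that split a
codon at phase 1 or 2, leaving a "bridged" codon half on each side of the
junction.  `intronalign` is a self-contained implementation of this
spliced-alignment problem for people building or evaluating gene-annotation
tools: it maps queries to candidate loci with a spaced-seed heuristic,
aligns them with an exact dynamic program, and scores predictions against
an annotation.

## The model

For a query `a = a0…a(m−1)` and genomic segment `b = b0…b(n−1)` the DP
state at `(i, j)` tracks three layers — `D` (residue `a(i−1)` aligned to
codon `b[j−3..j)`), `V` (unpaired residue) and `H` (unpaired in-frame
codon) — under an affine gap penalty `v + u·L`, plus intron states at all
three codon phases.  An intron opens at any potential donor, costs nothing
per nucleotide, and closes at any potential acceptor paying donor/acceptor
signal scores plus a length penalty in one of three precision modes:

* **FULL** — `round(α + β·ln ℓ)`, the log-affine length-dependent cost;
* **COARSE** — FULL evaluated at the geometric midpoint of a grain-sized
  length bin (a fully step-wise approximation);
* **CONSTANT** — a flat cost `IP0`, as most other spliced aligners use.

Alignment is semi-global: unaligned genomic flanks are free, query
terminal gaps are charged.  All scores are integers, so every reported
alignment decomposes into an exact sum of components — the engine asserts
this audit on every alignment it returns.

Traceback memory is controlled by the unidirectional Hirschberg methods.
A forward pass propagates, through every MAX operation, the coordinate at
which the best path crossed `k` intermediate rows (the vertical/horizontal
link arrays `VL`/`HL`); the `k+1` sub-rectangles those crossings delimit
are then re-filled at full resolution.  With 4-byte links and 2-byte
traceback cells the expected memory is

    M(k, m, n) = 16·n·k + 2·m·n·(k+1)⁻²  bytes,

minimised at `k̂(m) = (m/4)^⅓ − 1` — about 5.3 intermediates for a
1000-residue query.  When `M(k̂)` exceeds the budget `V_max` the engine
falls back to a recursive single-intermediate split whose subproblems
re-enter the same decision.  All linear-space algorithms reproduce the
full-matrix alignment exactly (same score, same gene model), which the
test suite verifies across hundreds of seeded instances.

## Worked example

```python
from intronalign import SequenceRecord, align_full, default_params, percent_identity

params = default_params("FULL")
genome = SequenceRecord(
    "locus",
    "ATG" + "GTAAGCCCCACCCCTCCCACCCCTACCCCTTCCCTTTTAG" + "AAAGTT",
    alphabet="nucleotide",
)
query = SequenceRecord("myprot", "MKV")
score, model = align_full(query, genome, params)
print(score)                 # 7
print(model.exon_intervals)  # [(0, 3), (43, 49)]
print(model.introns)         # [(3, 43, 'GT', 'AG', 7, 0)]
print(percent_identity(model.stats))  # 100.0
```

The query `MKV` aligns as two coding exons: `ATG` (M), then a 40 nt
`GT..AG` intron at codon phase 0, then `AAA GTT` (K, V).  The score 7 is
the three BLOSUM62 identities (5 + 5 + 4) minus the length-dependent
intron penalty `round(−15 + 6·ln 40) = 7`; the intron tuple reports
(start, end, donor, acceptor, penalty, phase).

## Command line

```
intronalign simulate --seed 7 --genes 20 -o sim/          # synthetic truth set
intronalign map -g sim/genome.fa -q sim/queries.fa -o out.gff3
intronalign align -g segments.fa -q queries.fa -o out.gff3  # side-by-side mode
intronalign eval --pred out.gff3 --truth sim/truth.gff3
```

`eval` reports mapping sensitivity (MS), gene-level sensitivity and
specificity (GN/GP — a gene counts only if *every* exon boundary is
exact), and exon-level sensitivity/specificity/F1 (EN/EP/EF).  Percent
identity is `100·#matches / (#matches + #mismatches + (#gaps + #unpaired)/2)`.

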