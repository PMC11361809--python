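"""Heuristic genome mapping: spaced seeds, HSP search, locus chaining.

Locating candidate gene loci before running the DP engine uses a
three-level recursive HSP (high-scoring pair) search on six-frame
translations of the genome under reduced amino-acid alphabets:

1. a genome-wide pass with the weight-3 seed "1101" on a 12-letter
   alphabet collects rough diagonals;
2. an intermediate pass refines each candidate window;
3. the final pass uses alphabet size 10, k-mer weight 4 and the spaced
   seed "11011".

Diagonals (j - 3i, within a shift tolerance) holding more seed hits than
a level-specific minimum are extended with the ungapped X-drop algorithm,
HSPs are chained colinearly (genomic gaps up to the maximum intron
length), and each maximal chain becomes a candidate locus window that the
spliced aligner then processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scoring import AA_INDEX, AA_ORDER, CODON2AA, SpeciesParams, encode_nucleotides, encode_protein
from .seqio import SequenceRecord


# ---------------------------------------------------------------------------
# Reduced alphabets and spaced seeds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpacedSeed:
    """A match pattern over {1,0}; 1 = sampled position, 0 = don't care."""

    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern or set(self.pattern) - {"0", "1"}:
            raise ValueError("seed pattern must be a non-empty 0/1 string")
        if self.pattern[0] != "1" or self.pattern[-1] != "1":
            raise ValueError("seed pattern must start and end with 1")

    @property
    def weight(self) -> int:
        return self.pattern.count("1")

    @property
    def span(self) -> int:
        return len(self.pattern)

    @property
    def sampled(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.pattern) if c == "1")


# groupings: hydrophobicity/charge clusters; the sizes are what matters,
# the exact groupings are a documented free choice.
_GROUPS = {
    10: ["LVIM", "C", "A", "G", "ST", "P", "FYW", "EDNQ", "KR", "H"],
    12: ["LVIM", "C", "A", "G", "ST", "P", "FY", "W", "ED", "NQ", "KR", "H"],
    8: ["LVIMC", "AG", "ST", "P", "FYW", "EDNQ", "KRH", "X"],
    20: list(AA_ORDER),
}


@dataclass(frozen=True)
class ReducedAlphabet:
    """Total deterministic mapping of the 20 amino acids onto fewer groups.

    X (and anything unknown) maps to a dedicated wildcard group with index
    ``size``; stop codons map to -1 and break seed keys.
    """

    size: int

    def __post_init__(self) -> None:
        if self.size not in _GROUPS:
            raise ValueError(f"no grouping of size {self.size} defined")

    @property
    def mapping(self) -> np.ndarray:
        """aa index (0..21) -> group index; X -> size, stop -> -1."""
        out = np.full(22, -1, dtype=np.int8)
        for gi, grp in enumerate(_GROUPS[self.size]):
            for ch in grp:
                if ch in AA_INDEX and AA_INDEX[ch] < 20:
                    out[AA_INDEX[ch]] = gi
        out[20] = self.size  # X wildcard group
        return out

    @property
    def n_symbols(self) -> int:
        return self.size + 1  # groups plus the wildcard


def reduce_sequence(protein: SequenceRecord | str, alphabet: ReducedAlphabet) -> np.ndarray:
    """Per-residue group substitution; length preserved."""
    res = protein.residues if isinstance(protein, SequenceRecord) else str(protein)
    enc = encode_protein(res)
    return alphabet.mapping[enc]


# ---------------------------------------------------------------------------
# Level parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LevelParams:
    seed: SpacedSeed
    alphabet: ReducedAlphabet
    min_hits: int       # a diagonal must hold MORE hits than this
    min_score: int      # HSP score cutoff, matrix units
    xdrop: int = 20
    shift_tol: int = 16  # diagonals are bucketed to this tolerance


LEVELS: dict[int, LevelParams] = {
    1: LevelParams(SpacedSeed("1101"), ReducedAlphabet(12), 6, 40, shift_tol=2),
    2: LevelParams(SpacedSeed("1101"), ReducedAlphabet(10), 2, 35, shift_tol=4),
    3: LevelParams(SpacedSeed("11011"), ReducedAlphabet(10), 0, 30, shift_tol=16),
}


# ---------------------------------------------------------------------------
# HSPs and loci
# ---------------------------------------------------------------------------

@dataclass
class HSP:
    """A scored ungapped diagonal segment, protein vs genome.

    ``(q0, q1)`` in residues, ``(g0, g1)`` in nucleotides on the indexed
    strand's forward coordinates, with g1-g0 == 3*(q1-q0); the diagonal
    index is g0 - 3*q0.
    """

    q0: int
    q1: int
    g0: int
    g1: int
    strand: str
    score: int
    level: int = 0

    def __post_init__(self) -> None:
        if self.g1 - self.g0 != 3 * (self.q1 - self.q0):
            raise ValueError("HSP intervals are not codon-consistent")

    @property
    def diagonal(self) -> int:
        return self.g0 - 3 * self.q0


@dataclass
class CandidateLocus:
    """A genomic window worth running the spliced aligner over."""

    w0: int
    w1: int
    strand: str
    hsps: list[HSP] = field(default_factory=list)
    chain_score: int = 0


# ---------------------------------------------------------------------------
# Seed index
# ---------------------------------------------------------------------------

class SeedIndex:
    """Spaced-seed key -> positions over six-frame reduced translations.

    For each strand the genome is translated in all three frames; every
    seed window whose span is free of stop codons contributes one key at
    the nucleotide position of its first codon.
    """

    def __init__(self, genome: SequenceRecord | str, seed: SpacedSeed,
                 alphabet: ReducedAlphabet, both_strands: bool = True):
        self.seed = seed
        self.alphabet = alphabet
        res = genome.residues if isinstance(genome, SequenceRecord) else str(genome)
        self.n = len(res)
        self.strands: dict[str, dict[int, list[int]]] = {}
        self._taa: dict[str, np.ndarray] = {}
        self.strands["+"] = self._index_strand(res)
        if both_strands:
            rc = SequenceRecord("rc", res, alphabet="nucleotide").reverse_complement()
            self.strands["-"] = self._index_strand(rc.residues)

    def translation(self, strand: str) -> np.ndarray:
        """aa column index of the codon starting at each nt position."""
        return self._taa[strand]

    def _index_strand(self, res: str) -> dict[int, list[int]]:
        nt = encode_nucleotides(res)
        n = len(nt)
        taa = np.full(max(n - 2, 0), 21, dtype=np.int8)
        if n >= 3:
            c1, c2, c3 = nt[:-2], nt[1:-1], nt[2:]
            has_n = (c1 == 4) | (c2 == 4) | (c3 == 4)
            idx = (16 * np.where(has_n, 0, c1) + 4 * np.where(has_n, 0, c2)
                   + np.where(has_n, 0, c3)).astype(np.int64)
            taa = CODON2AA[idx].astype(np.int8)
            taa[has_n] = 20
        key = "+" if "+" not in self._taa else "-"
        self._taa[key] = taa
        index: dict[int, list[int]] = {}
        red_map = self.alphabet.mapping
        span = self.seed.span
        sampled = self.seed.sampled
        base = self.alphabet.n_symbols
        for f in range(3):
            codes = red_map[taa[f::3]] if len(taa) > f else np.empty(0, dtype=np.int8)
            L = len(codes)
            for t in range(L - span + 1):
                window = codes[t : t + span]
                if (window < 0).any():  # stop codon inside the span
                    continue
                k = 0
                for s in sampled:
                    k = k * base + int(window[s])
                index.setdefault(k, []).append(f + 3 * t)
        return index

    def key_of(self, reduced: np.ndarray, at: int) -> int | None:
        span = self.seed.span
        window = reduced[at : at + span]
        if len(window) < span or (window < 0).any():
            return None
        k = 0
        base = self.alphabet.n_symbols
        for s in self.seed.sampled:
            k = k * base + int(window[s])
        return k


# ---------------------------------------------------------------------------
# Ungapped extension and HSP search
# ---------------------------------------------------------------------------

def ungapped_extend(q_enc: np.ndarray, taa: np.ndarray, subm: np.ndarray,
                    i_seed: int, j_seed: int, span_aa: int, xdrop: int,
                    strand: str = "+", level: int = 0) -> HSP:
    """Extend a seed hit along its diagonal with the X-drop rule.

    Starting from the seed window (query residues [i_seed, i_seed+span)
    against codons from nt position j_seed), accumulate substitution
    scores left and right, stopping once the running score falls ``xdrop``
    below the running maximum, and return the maximum-scoring segment.
    """
    from ._kernel import xdrop_extend

    left_start, right_end, score = xdrop_extend(
        q_enc, taa, subm.astype(np.int64, copy=False),
        int(i_seed), int(j_seed), int(xdrop),
    )
    q0, q1 = int(left_start), max(int(right_end), int(left_start) + 1)
    score = int(score)
    if q1 <= q0:
        q0, q1 = i_seed, i_seed + 1
    g0 = j_seed + 3 * (q0 - i_seed)
    g1 = j_seed + 3 * (q1 - i_seed)
    return HSP(q0, q1, g0, g1, strand, score, level)


def find_hsps(query: SequenceRecord, index: SeedIndex, level: int,
              params: SpeciesParams,
              window: tuple[str, int, int] | None = None) -> list[HSP]:
    """Collect spaced-seed hits and extend the well-hit diagonals.

    ``window`` optionally restricts the search to (strand, g0, g1) in the
    indexed strand's coordinates.  HSPs below the level's score cutoff
    are discarded; at most one HSP is kept per seeded diagonal bucket.
    """
    lp = LEVELS[level]
    if index.seed != lp.seed or index.alphabet != lp.alphabet:
        raise ValueError("index was built with different level parameters")
    reduced = reduce_sequence(query, lp.alphabet)
    q_enc = encode_protein(query.residues)
    subm = params.scheme.matrix.astype(np.int64)
    out: list[HSP] = []
    strands = [window[0]] if window else list(index.strands)
    for strand in strands:
        idx = index.strands[strand]
        taa = index.translation(strand)
        hits: dict[int, list[tuple[int, int]]] = {}
        for i in range(len(reduced) - lp.seed.span + 1):
            k = index.key_of(reduced, i)
            if k is None or k not in idx:
                continue
            for j in idx[k]:
                if window and not (window[1] <= j < window[2]):
                    continue
                d = j - 3 * i
                hits.setdefault(d // (3 * lp.shift_tol), []).append((i, j))
        seen: set[tuple[int, int]] = set()
        covered: dict[int, int] = {}  # exact diagonal -> q index covered so far
        for bucket, pairs in hits.items():
            if len(pairs) <= lp.min_hits:
                continue
            pairs.sort()
            for i, j in pairs:
                d = j - 3 * i
                if covered.get(d, -1) >= i:
                    continue  # inside an already-extended HSP on this diagonal
                hsp = ungapped_extend(q_enc, taa, subm, i, j, lp.seed.span,
                                      lp.xdrop, strand, level)
                covered[d] = max(covered.get(d, -1), hsp.q1 - 1, i)
                key = (hsp.q0, hsp.g0)
                if key in seen:
                    continue
                seen.add(key)
                if hsp.score >= lp.min_score:
                    out.append(hsp)
    out.sort(key=lambda h: (h.strand, h.g0, h.q0))
    return out


def verify_hsp(hsp: HSP, q_enc: np.ndarray, taa: np.ndarray,
               subm: np.ndarray) -> int:
    """Recompute an HSP's score by direct summation over its segment."""
    total = 0
    for i in range(hsp.q0, hsp.q1):
        j = hsp.g0 + 3 * (i - hsp.q0)
        total += int(subm[q_enc[i], taa[j]])
    return total


# ---------------------------------------------------------------------------
# Chaining
# ---------------------------------------------------------------------------

def chain_to_loci(hsps: list[HSP], max_intron: int = 50000,
                  margin: int = 10000, n: int | None = None) -> list[CandidateLocus]:
    """Greedy colinear chaining into candidate locus windows.

    HSPs chain when both coordinates increase and the genomic gap stays
    within the maximum intron length; each maximal chain's window is
    expanded by the margin and overlapping windows on one strand merge.
    """
    loci: list[CandidateLocus] = []
    for strand in ("+", "-"):
        subset = sorted((h for h in hsps if h.strand == strand),
                        key=lambda h: (h.g0, h.q0))
        if not subset:
            continue
        nh = len(subset)
        best = [h.score for h in subset]
        prev = [-1] * nh
        for b in range(nh):
            hb = subset[b]
            for a in range(b):
                ha = subset[a]
                if ha.g1 > hb.g0 or hb.g0 - ha.g1 > max_intron:
                    continue
                # mild cost per kb of genomic gap keeps distant noise HSPs
                # from inflating windows while real introns chain freely
                gap_cost = (hb.g0 - ha.g1) // 2000
                if ha.q1 <= hb.q0:
                    cand = best[a] + hb.score - gap_cost
                elif ha.q0 < hb.q0:
                    # mild overlap in query (common at exon borders)
                    cand = best[a] + hb.score // 2 - gap_cost
                else:
                    continue
                if cand > best[b]:
                    best[b] = cand
                    prev[b] = a
        used = [False] * nh
        order = sorted(range(nh), key=lambda b: -best[b])
        for b in order:
            if used[b]:
                continue
            chain = []
            cur = b
            while cur != -1 and not used[cur]:
                chain.append(subset[cur])
                used[cur] = True
                cur = prev[cur]
            chain.reverse()
            w0 = min(h.g0 for h in chain) - margin
            w1 = max(h.g1 for h in chain) + margin
            w0 = max(0, w0)
            if n is not None:
                w1 = min(n, w1)
            loci.append(CandidateLocus(w0, w1, strand, chain,
                                       sum(h.score for h in chain)))
    # merge overlapping windows per strand
    merged: list[CandidateLocus] = []
    for strand in ("+", "-"):
        subset = sorted((l for l in loci if l.strand == strand),
                        key=lambda l: l.w0)
        for loc in subset:
            if merged and merged[-1].strand == strand and \
                    loc.w0 <= merged[-1].w1:
                last = merged[-1]
                last.w1 = max(last.w1, loc.w1)
                if loc.chain_score > last.chain_score:
                    last.hsps = loc.hsps
                    last.chain_score = loc.chain_score
            else:
                merged.append(loc)
    merged.sort(key=lambda l: -l.chain_score)
    return merged


# ---------------------------------------------------------------------------
# The mapping -> alignment pipeline
# ---------------------------------------------------------------------------

def map_query(query: SequenceRecord, genome: SequenceRecord,
              params: SpeciesParams,
              index1: SeedIndex | None = None,
              max_intron: int = 50000, margin: int = 10000,
              max_loci: int = 4) -> list[CandidateLocus]:
    """Three-level recursive HSP search producing candidate loci.

    Level 1 runs genome-wide; each resulting window is refined with the
    level-3 seed (the level-2 pass re-scores the window and is skipped
    when level 1 already produced a single compact chain).
    """
    if index1 is None:
        index1 = SeedIndex(genome, LEVELS[1].seed, LEVELS[1].alphabet)
    hsps1 = find_hsps(query, index1, 1, params)
    rough = chain_to_loci(hsps1, max_intron, margin, n=len(genome.residues))
    if not rough:
        return []
    out: list[CandidateLocus] = []
    for loc in rough[:max_loci]:
        sub = genome.residues[loc.w0:loc.w1]
        if loc.strand == "-":
            sub = SequenceRecord("w", sub, alphabet="nucleotide") \
                .reverse_complement().residues
        subrec = SequenceRecord("w", sub, alphabet="nucleotide")
        idx3 = SeedIndex(subrec, LEVELS[3].seed, LEVELS[3].alphabet,
                         both_strands=False)
        hsps3 = find_hsps(query, idx3, 3, params, window=("+", 0, len(sub)))
        refined = chain_to_loci(hsps3, max_intron, margin=500, n=len(sub))
        if not refined:
            continue
        best = refined[0]
        if loc.strand == "+":
            w0 = loc.w0 + best.w0
            w1 = loc.w0 + best.w1
        else:
            w0 = loc.w1 - best.w1
            w1 = loc.w1 - best.w0
        out.append(CandidateLocus(w0, w1, loc.strand, best.hsps,
                                  best.chain_score))
    out.sort(key=lambda l: -l.chain_score)
    return out


def map_and_align(query: SequenceRecord, genome: SequenceRecord,
                  params: SpeciesParams, config=None,
                  index1: SeedIndex | None = None,
                  max_intron: int = 50000, margin: int = 10000):
    """Map a query to candidate loci and splice-align the best one.

    Returns ``(gene, model, locus)`` where ``gene`` is an
    :class:`~intronalign.seqio.AnnotatedGene` in genome coordinates (exons
    flipped back for minus-strand loci), or ``(None, None, None)`` when
    mapping finds nothing or the alignment falls below the minimum report
    score.
    """
    from .linear_space import align_auto
    from .seqio import AnnotatedGene, RunConfig

    config = config or RunConfig(min_report_score=0)
    loci = map_query(query, genome, params, index1, max_intron, margin)
    best = None
    for locus in loci[:2]:
        seg = genome.residues[locus.w0:locus.w1]
        if locus.strand == "-":
            seg = SequenceRecord("w", seg, alphabet="nucleotide") \
                .reverse_complement().residues
        segrec = SequenceRecord(genome.id, seg, alphabet="nucleotide")
        score, model, _plan = align_auto(query, segrec, params, config)
        if model is None:
            continue
        if best is None or score > best[0]:
            best = (score, model, locus)
    if best is None:
        return None, None, None
    score, model, locus = best
    if locus.strand == "+":
        exons = [(locus.w0 + a, locus.w0 + b) for a, b in model.exon_intervals]
    else:
        exons = [(locus.w1 - b, locus.w1 - a) for a, b in model.exon_intervals]
    gene = AnnotatedGene(query.id, genome.id, locus.strand, sorted(exons))
    return gene, model, locus
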