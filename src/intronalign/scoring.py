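"""Scoring models for codon-aware spliced alignment.

Three ingredients drive the alignment objective:

* an amino-acid substitution matrix applied to (query residue, translated
  genomic codon) pairs, with an affine gap penalty (open ``v``, extend ``u``
  per residue vertically / per codon horizontally);
* a splice-site model that decides which genomic dinucleotides may open
  (donor) or close (acceptor) an intron, each with an additive signal score.
  The canonical classes are GT..AG, GC..AG and AT..AC; AT donors pair only
  with AC acceptors;
* an intron penalty as a function of intron length, in one of three
  precision modes: FULL (log-affine in length), COARSE (FULL evaluated at
  the geometric midpoint of a fixed-size length bin) and CONSTANT
  (length-independent).

All scores are integers ("matrix units"); FULL/COARSE penalties are rounded
to the nearest integer so that every alignment score decomposes into an
exact sum of integer components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

# ---------------------------------------------------------------------------
# Alphabets and the genetic code
# ---------------------------------------------------------------------------

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"  # 20 amino acids, index 0..19
AA_X = 20          # wildcard amino acid (also the image of any codon with N)
AA_STOP = 21       # in-frame stop codon pseudo-residue
N_AA_COLS = 22

AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
AA_INDEX["X"] = AA_X

NT_ORDER = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NT_ORDER)}
NT_N = 4

#: codon index (16*c1 + 4*c2 + c3 over ACGT codes) -> amino-acid index
CODON2AA = np.empty(64, dtype=np.int8)


def _build_codon_table() -> None:
    table = CodonTable.unambiguous_dna_by_id[1]  # the standard code
    for i1, n1 in enumerate(NT_ORDER):
        for i2, n2 in enumerate(NT_ORDER):
            for i3, n3 in enumerate(NT_ORDER):
                codon = n1 + n2 + n3
                idx = 16 * i1 + 4 * i2 + i3
                if codon in table.stop_codons:
                    CODON2AA[idx] = AA_STOP
                else:
                    CODON2AA[idx] = AA_INDEX[table.forward_table[codon]]


_build_codon_table()

DEFAULT_GAP_OPEN = 8
DEFAULT_GAP_EXTEND = 2
DEFAULT_STOP_SCORE = -50
DEFAULT_MIN_INTRON = 30
DEFAULT_IP0 = 20
DEFAULT_ALPHA = -15.0
DEFAULT_BETA = 6.0
DEFAULT_GRAIN = 1024

# donor/acceptor class codes used throughout the DP
DONOR_GT, DONOR_GC, DONOR_AT = 0, 1, 2
ACC_AG, ACC_AC = 0, 1
#: donor class -> the only acceptor class it may pair with
DONOR_PAIRING = {DONOR_GT: ACC_AG, DONOR_GC: ACC_AG, DONOR_AT: ACC_AC}

_DONOR_DINUC = {"GT": DONOR_GT, "GC": DONOR_GC, "AT": DONOR_AT}
_ACC_DINUC = {"AG": ACC_AG, "AC": ACC_AC}


def load_blosum62() -> np.ndarray:
    """BLOSUM62 as an int16 matrix over (21 residues, 22 codon images).

    Rows: the 20 amino acids in :data:`AA_ORDER` order plus X.  Columns: the
    same 21 plus a stop column whose entries are filled in later from the
    scheme's stop score.
    """
    bl = substitution_matrices.load("BLOSUM62")
    m = np.zeros((21, N_AA_COLS), dtype=np.int16)
    letters = AA_ORDER + "X"
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            m[i, j] = int(bl[a][b])
    return m


@dataclass
class ScoringScheme:
    """Substitution matrix plus affine gap costs.

    ``gap_open`` (v) and ``gap_extend`` (u) are non-negative costs; a gap of
    length L costs v + u*L, where the unit is one residue for vertical gaps
    and one in-frame codon for horizontal gaps.  ``pieces`` is the number of
    segments of the piecewise-linear gap penalty; the affine case fixed here
    has two.
    """

    matrix: np.ndarray = field(default_factory=load_blosum62)
    gap_open: int = DEFAULT_GAP_OPEN
    gap_extend: int = DEFAULT_GAP_EXTEND
    stop_score: int = DEFAULT_STOP_SCORE
    pieces: int = 2

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int16)
        if self.matrix.shape not in {(21, 21), (21, N_AA_COLS)}:
            raise ValueError(f"matrix must be 21x21 or 21x22, got {self.matrix.shape}")
        if self.matrix.shape == (21, 21):
            m = np.empty((21, N_AA_COLS), dtype=np.int16)
            m[:, :21] = self.matrix
            self.matrix = m
        self.matrix[:, AA_STOP] = self.stop_score
        if not np.array_equal(self.matrix[:21, :21], self.matrix[:21, :21].T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap costs must be non-negative")
        if self.pieces != 2:
            raise ValueError("only the affine case (pieces=2) is supported")

    def score(self, residue_index: int, aa_col: int) -> int:
        return int(self.matrix[residue_index, aa_col])


@dataclass
class SpliceModel:
    """Which dinucleotides open/close introns, and at what signal score.

    A site is *potential* iff its dinucleotide matches one of the listed
    rules and its signal score exceeds ``threshold``.  The scores default to
    ranking GT..AG above GC..AG above AT..AC, mirroring the observed >98%
    dominance of canonical classes.
    """

    donor_scores: dict[str, int] = field(
        default_factory=lambda: {"GT": 0, "GC": -6, "AT": -8}
    )
    acceptor_scores: dict[str, int] = field(
        default_factory=lambda: {"AG": 0, "AC": -2}
    )
    threshold: int = -10

    def __post_init__(self) -> None:
        for d in self.donor_scores:
            if d not in _DONOR_DINUC:
                raise ValueError(f"unsupported donor dinucleotide {d!r}")
        for a in self.acceptor_scores:
            if a not in _ACC_DINUC:
                raise ValueError(f"unsupported acceptor dinucleotide {a!r}")


@dataclass
class IntronPenaltyModel:
    """Length-dependent intron cost in FULL, COARSE or CONSTANT precision.

    FULL charges round(alpha + beta*ln(L)) for an intron of length L >= min_length
    (clamped at zero); CONSTANT charges ip0 regardless of length; COARSE
    charges the FULL cost evaluated at the geometric midpoint of the
    grain-sized bin containing L.  Introns shorter than min_length are forbidden.
    An optional empirical (length, cost) table overrides the log-affine form
    in FULL mode via stepwise lookup.
    """

    mode: str = "FULL"
    min_length: int = DEFAULT_MIN_INTRON
    ip0: int = DEFAULT_IP0
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    grain: int = DEFAULT_GRAIN
    table: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.mode = self.mode.upper()
        if self.mode not in {"FULL", "COARSE", "CONSTANT"}:
            raise ValueError(f"unknown intron penalty mode {self.mode!r}")
        if self.min_length < 1:
            raise ValueError("min_length must be positive")
        if self.mode == "COARSE" and self.grain < 1:
            raise ValueError("grain must be positive")
        if self.ip0 < 0:
            raise ValueError("constant intron penalty must be non-negative")

    # -- scalar penalty ----------------------------------------------------
    def _full(self, length: float) -> int:
        if self.table is not None:
            cost = self.table[0][1]
            for ell, c in self.table:
                if length >= ell:
                    cost = c
                else:
                    break
            return max(0, int(cost))
        return max(0, round(self.alpha + self.beta * math.log(length)))

    def penalty(self, length: int) -> float:
        """Cost of an intron of ``length`` nt; +inf below the minimum length."""
        if length < self.min_length:
            return math.inf
        if self.mode == "CONSTANT":
            return self.ip0
        if self.mode == "FULL":
            return self._full(length)
        # COARSE: representative length is the geometric midpoint of the bin
        k = length // self.grain
        lo = max(k * self.grain, 1)
        rep = math.sqrt(lo * (k + 1) * self.grain)
        return self._full(max(rep, self.min_length))

    def penalty_table(self, max_length: int, neg_inf: int) -> np.ndarray:
        """Integer penalties for lengths 0..max_length (forbidden -> -neg sentinel)."""
        out = np.empty(max_length + 1, dtype=np.int32)
        out[: self.min_length] = -neg_inf  # subtracted later: -> -inf score
        if self.mode == "CONSTANT":
            out[self.min_length:] = self.ip0
            return out
        lengths = np.arange(self.min_length, max_length + 1)
        if self.mode == "COARSE":
            k = lengths // self.grain
            lo = np.maximum(k * self.grain, 1)
            rep = np.maximum(np.sqrt(lo * (k + 1) * self.grain), self.min_length)
        else:
            rep = lengths
        if self.table is not None:
            vals = np.array([self._full(r) for r in rep], dtype=np.int32)
        else:
            vals = np.maximum(
                0, np.rint(self.alpha + self.beta * np.log(rep)).astype(np.int64)
            ).astype(np.int32)
        out[self.min_length:] = vals
        return out


@dataclass
class SpeciesParams:
    """The full species-specific parameter bundle handed to the aligner."""

    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    splice: SpliceModel = field(default_factory=SpliceModel)
    intron: IntronPenaltyModel = field(default_factory=IntronPenaltyModel)

    def with_mode(self, mode: str) -> "SpeciesParams":
        """Copy of the parameters with the intron-penalty mode replaced.

        Accepts FULL/COARSE/CONSTANT or the a0..a3 aliases (a0 and a1 both
        denote full precision and must behave identically; a2 is coarse,
        a3 constant).
        """
        mode = mode.upper()
        aliases = {"A0": "FULL", "A1": "FULL", "A2": "COARSE", "A3": "CONSTANT"}
        mode = aliases.get(mode, mode)
        return SpeciesParams(
            scheme=self.scheme,
            splice=self.splice,
            intron=replace(self.intron, mode=mode),
        )


def default_params(mode: str = "FULL") -> SpeciesParams:
    return SpeciesParams().with_mode(mode)


# ---------------------------------------------------------------------------
# Sequence encoding helpers
# ---------------------------------------------------------------------------

def encode_protein(residues: str) -> np.ndarray:
    """Residue string -> int8 indices (unknowns map to X)."""
    out = np.empty(len(residues), dtype=np.int8)
    for i, ch in enumerate(residues):
        out[i] = AA_INDEX.get(ch, AA_X)
    return out


def encode_nucleotides(residues: str) -> np.ndarray:
    out = np.empty(len(residues), dtype=np.int8)
    for i, ch in enumerate(residues):
        out[i] = NT_INDEX.get(ch, NT_N)
    return out


def codon_aa_indices(nt: np.ndarray) -> np.ndarray:
    """Per-end-position translation of a nucleotide index array.

    ``out[j]`` is the amino-acid column index of codon ``nt[j-3:j]`` for
    j >= 3 (X for any codon containing N) and -1 for j < 3.
    """
    n = len(nt)
    out = np.full(n + 1, -1, dtype=np.int8)
    if n >= 3:
        c1, c2, c3 = nt[:-2], nt[1:-1], nt[2:]
        has_n = (c1 == NT_N) | (c2 == NT_N) | (c3 == NT_N)
        idx = (16 * np.where(has_n, 0, c1) + 4 * np.where(has_n, 0, c2)
               + np.where(has_n, 0, c3)).astype(np.int64)
        aa = CODON2AA[idx].astype(np.int8)
        aa[has_n] = AA_X
        out[3:] = aa
    return out


def substitution_score(residue: str, codon: str, scheme: ScoringScheme) -> int:
    """Score of aligning one query residue against a genomic codon.

    The codon is translated with the standard genetic code; stop codons
    score the scheme's stop score and any codon containing N scores as X.
    """
    if len(codon) != 3:
        raise ValueError("codon must be 3 nucleotides")
    nt = encode_nucleotides(codon.upper())
    col = codon_aa_indices(nt)[3]
    return scheme.score(AA_INDEX.get(residue.upper(), AA_X), int(col))


def find_splice_sites(
    nt_or_record, model: SpliceModel
) -> tuple[list[tuple[int, int, int]], list[tuple[int, int, int]]]:
    """Locate potential donor and acceptor sites on a nucleotide sequence.

    Accepts a :class:`~intronalign.seqio.SequenceRecord` or a raw string /
    int8 array.  Returns ``(donors, acceptors)`` where each donor is
    ``(position, class, score)`` with ``position`` the 0-based index of the
    first intron base (the dinucleotide start), and each acceptor is
    ``(position, class, score)`` with ``position`` the index one past the
    last intron base (the dinucleotide occupies ``position-2:position``).
    Sites whose signal score does not exceed the threshold are excluded.
    """
    if hasattr(nt_or_record, "residues"):
        seq = nt_or_record.residues
    elif isinstance(nt_or_record, np.ndarray):
        seq = "".join("ACGTN"[c] for c in nt_or_record)
    else:
        seq = str(nt_or_record)
    seq = seq.upper()
    donors: list[tuple[int, int, int]] = []
    acceptors: list[tuple[int, int, int]] = []
    for dinuc, cls in _DONOR_DINUC.items():
        if dinuc not in model.donor_scores:
            continue
        sc = model.donor_scores[dinuc]
        if sc <= model.threshold:
            continue
        start = seq.find(dinuc)
        while start != -1:
            donors.append((start, cls, sc))
            start = seq.find(dinuc, start + 1)
    for dinuc, cls in _ACC_DINUC.items():
        if dinuc not in model.acceptor_scores:
            continue
        sc = model.acceptor_scores[dinuc]
        if sc <= model.threshold:
            continue
        start = seq.find(dinuc)
        while start != -1:
            acceptors.append((start + 2, cls, sc))
            start = seq.find(dinuc, start + 1)
    donors.sort()
    acceptors.sort()
    return donors, acceptors


def intron_penalty(length: int, model: IntronPenaltyModel) -> float:
    """Cost of an intron of the given length under the model's mode."""
    return model.penalty(length)
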