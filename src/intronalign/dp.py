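"""Codon-aware spliced-alignment engine (full-matrix and banded).

The alignment is semi-global: unaligned genomic prefix/suffix is free,
query terminal gaps are penalized.  The optimum is taken over paths built
from diagonal moves (one query residue against one in-frame codon),
vertical moves (unpaired residue), horizontal moves (unpaired codon),
and intron moves that open at a potential donor site at codon phase 0, 1
or 2, jump at zero per-nucleotide cost, and close at a potential acceptor
paying the mode-dependent intron penalty plus both signal scores.  A
phase-p intron splits a codon into p nucleotides before the donor and 3-p
after the acceptor ("bridged codon"), scored as a single substitution.
A deletion in the query may stride across an intron: the gap re-opens on
the far side without a second gap-open charge.

Every returned :class:`GeneModel` carries its move list, and
:meth:`GeneModel.recompute_score` re-adds the integer components
(substitutions, gap costs, intron penalties, signal scores); the result
equals the DP score exactly, which the drivers assert on every call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from ._kernel import LAYER_D, LAYER_H, LAYER_V, NEG, NEG_HALF
from .evaluation import AlignmentStats
from .scoring import (
    CODON2AA,
    SpeciesParams,
    codon_aa_indices,
    encode_nucleotides,
    encode_protein,
    find_splice_sites,
)
from .seqio import RunConfig, SequenceRecord


class ContractViolation(ValueError):
    pass


# ---------------------------------------------------------------------------
# Instrumented traceback-memory meter
# ---------------------------------------------------------------------------

class TracebackMeter:
    """Counts bytes of traceback/link storage currently and at peak.

    This is an algorithmic counter (2 bytes per traceback cell, 16 bytes
    per link-array column per intermediate), not OS memory.
    """

    def __init__(self) -> None:
        self.current = 0
        self.peak = 0

    def reset(self) -> None:
        self.current = 0
        self.peak = 0

    def alloc(self, nbytes: int) -> None:
        self.current += nbytes
        if self.current > self.peak:
            self.peak = self.current

    def free(self, nbytes: int) -> None:
        self.current -= nbytes


METER = TracebackMeter()

# a counter of DP cells recomputed during traceback reconstruction
class CellCounter:
    def __init__(self) -> None:
        self.cells = 0

    def reset(self) -> None:
        self.cells = 0

    def add(self, n: int) -> None:
        self.cells += n


RECALC = CellCounter()


# ---------------------------------------------------------------------------
# Segment context: encoded arrays shared by all passes over one genomic segment
# ---------------------------------------------------------------------------

@dataclass
class SegmentContext:
    seq_id: str
    residues: str
    nt: np.ndarray
    caa: np.ndarray
    dpos: np.ndarray
    dcls: np.ndarray
    dsc: np.ndarray
    acls_arr: np.ndarray
    asc_arr: np.ndarray
    dsc_at: np.ndarray
    pen: np.ndarray
    subm: np.ndarray
    v: int
    u: int
    lmin: int
    params: SpeciesParams

    @classmethod
    def build(cls, segment, params: SpeciesParams) -> "SegmentContext":
        if isinstance(segment, SequenceRecord):
            seq_id, residues = segment.id, segment.residues
        else:
            seq_id, residues = "segment", str(segment).upper()
        nt = encode_nucleotides(residues)
        n = len(nt)
        caa = codon_aa_indices(nt)
        donors, acceptors = find_splice_sites(residues, params.splice)
        dpos = np.array([d[0] for d in donors], dtype=np.int64)
        dcls = np.array([d[1] for d in donors], dtype=np.int8)
        dsc = np.array([d[2] for d in donors], dtype=np.int64)
        acls_arr = np.full(n + 1, -1, dtype=np.int8)
        asc_arr = np.zeros(n + 1, dtype=np.int64)
        for pos, c, s in acceptors:
            acls_arr[pos] = c
            asc_arr[pos] = s
        dsc_at = np.zeros(n + 1, dtype=np.int64)
        for pos, _c, s in donors:
            dsc_at[pos] = s
        big = 1 << 28
        pen = params.intron.penalty_table(max(n, params.intron.min_length), big)
        return cls(
            seq_id, residues, nt, caa, dpos, dcls, dsc, acls_arr, asc_arr,
            dsc_at, pen, params.scheme.matrix.astype(np.int64),
            int(params.scheme.gap_open), int(params.scheme.gap_extend),
            int(params.intron.min_length), params,
        )

    @property
    def n(self) -> int:
        return len(self.nt)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A spliced alignment as ordered coding exons with a decomposable score.

    Coordinates are 0-based half-open relative to the aligned segment.
    ``moves`` is the exact DP path: tuples ('D', i, j), ('V', i, j),
    ('H', i, j) with (i, j) the cell *after* the move, ('I', i, j_donor,
    j_acceptor, phase) for an intron bridging a codon, and
    ('HI', i, j_donor, j_acceptor) for an intron inside a deletion.
    """

    query_id: str
    target_id: str
    strand: str
    score: int
    exons: list[tuple[int, int, int]]            # (start, end, codon phase)
    introns: list[tuple[int, int, str, str, int, int]]  # (s, e, don, acc, pen, phase)
    aligned_pairs: list[tuple[int, tuple[int, int]]]
    stats: AlignmentStats
    moves: list[tuple] = field(default_factory=list, repr=False)
    query_start: int = 0
    query_end: int = 0
    genome_start: int = 0
    genome_end: int = 0
    truncated: bool = False

    def recompute_score(self, query: str, ctx: SegmentContext) -> int:
        """Sum of integer score components along the path (the audit)."""
        q = encode_protein(query)
        subm = ctx.subm
        score = 0
        prev = "start"
        for mv in self.moves:
            kind = mv[0]
            if kind == "D":
                _, i, j = mv
                score += int(subm[q[i - 1], ctx.caa[j]])
            elif kind == "V":
                score -= ctx.u + (ctx.v if prev != "V" else 0)
            elif kind == "H":
                score -= ctx.u + (ctx.v if prev not in ("H", "HI") else 0)
            elif kind == "I":
                _, i, jd, ja, p = mv
                bridged = self._bridged_col(ctx, jd, ja, p)
                score += int(ctx.dsc_at[jd]) + int(ctx.asc_arr[ja])
                score -= int(ctx.pen[ja - jd])
                score += int(subm[q[i - 1], bridged])
            elif kind == "HI":
                _, i, jd, ja = mv
                score += int(ctx.dsc_at[jd]) + int(ctx.asc_arr[ja])
                score -= int(ctx.pen[ja - jd]) + ctx.u
            prev = kind
        return score

    @staticmethod
    def _bridged_col(ctx: SegmentContext, jd: int, ja: int, p: int) -> int:
        nts = list(ctx.nt[jd - p : jd]) + list(ctx.nt[ja : ja + 3 - p])
        if any(x == 4 for x in nts):
            return 20
        return int(CODON2AA[16 * nts[0] + 4 * nts[1] + nts[2]])

    @property
    def exon_intervals(self) -> list[tuple[int, int]]:
        return [(s, e) for s, e, _p in self.exons]

    @property
    def num_exons(self) -> int:
        return len(self.exons)


def _moves_to_model(
    moves: list[tuple],
    query: SequenceRecord,
    ctx: SegmentContext,
    score: int,
    start_j: int,
    truncated: bool = False,
) -> GeneModel:
    """Assemble exons, introns, aligned pairs and statistics from a DP path."""
    q = encode_protein(query.residues)
    exons: list[tuple[int, int, int]] = []
    introns: list[tuple[int, int, str, str, int, int]] = []
    pairs: list[tuple[int, tuple[int, int]]] = []
    exon_start = start_j
    cum_coding = 0

    first_d = last_d = None
    for idx, mv in enumerate(moves):
        if mv[0] in ("D", "I"):
            if first_d is None:
                first_d = idx
            last_d = idx

    matches = mismatches = gaps = unpaired = 0
    cur_j = start_j
    for idx, mv in enumerate(moves):
        kind = mv[0]
        if kind == "D":
            _, i, j = mv
            aa = int(ctx.caa[j])
            if aa == int(q[i - 1]) and aa < 20:
                matches += 1
            else:
                mismatches += 1
            pairs.append((i - 1, (j - 3, j)))
            cum_coding += 3
            cur_j = j
        elif kind == "V":
            if first_d is not None and first_d <= idx <= last_d:
                gaps += 1
            else:
                unpaired += 1
        elif kind == "H":
            gaps += 1
            cum_coding += 3
            cur_j = mv[2]
        elif kind == "I":
            _, i, jd, ja, p = mv
            exons.append((exon_start, jd, (cum_coding - p) % 3 if exons else 0))
            don = ctx.residues[jd : jd + 2]
            acc = ctx.residues[ja - 2 : ja]
            introns.append((jd, ja, don, acc, int(ctx.pen[ja - jd]), p))
            exon_start = ja
            aa = GeneModel._bridged_col(ctx, jd, ja, p)
            if aa == int(q[i - 1]) and aa < 20:
                matches += 1
            else:
                mismatches += 1
            if p:
                pairs.append((i - 1, (jd - p, jd)))
            pairs.append((i - 1, (ja, ja + 3 - p)))
            cum_coding += 3
            cur_j = ja + 3 - p
        elif kind == "HI":
            _, i, jd, ja = mv
            exons.append((exon_start, jd, 0))
            don = ctx.residues[jd : jd + 2]
            acc = ctx.residues[ja - 2 : ja]
            introns.append((jd, ja, don, acc, int(ctx.pen[ja - jd]), 0))
            exon_start = ja
            gaps += 1
            cum_coding += 3
            cur_j = ja + 3

    exons.append((exon_start, cur_j, 0))
    # recompute phases from cumulative exon lengths
    phased = []
    cum = 0
    for s, e, _ph in exons:
        phased.append((s, e, cum % 3))
        cum += e - s
    exons = phased

    q_rows = [mv[1] for mv in moves if mv[0] in ("D", "V", "I")]
    q_start = (q_rows[0] - 1) if q_rows else 0
    q_end = q_rows[-1] if q_rows else 0

    stats = AlignmentStats(matches, mismatches, gaps, unpaired)
    return GeneModel(
        query_id=query.id,
        target_id=ctx.seq_id,
        strand="+",
        score=int(score),
        exons=exons,
        introns=introns,
        aligned_pairs=pairs,
        stats=stats,
        moves=moves,
        query_start=q_start,
        query_end=q_end,
        genome_start=start_j,
        genome_end=cur_j,
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Traceback
# ---------------------------------------------------------------------------

def _walk_tb(tb, dclose, hiclose, ilo, jlo, w, end_r, end_c, end_l):
    """Follow stored argmax moves from the end cell back to the start.

    Returns the move list in forward order (absolute coordinates: query
    rows offset by ``ilo``, genomic columns by ``jlo``) and the absolute
    start column.
    """
    moves: list[tuple] = []
    r, c, L = end_r, end_c, end_l
    while True:
        code = int(tb[r, c])
        j = jlo + c
        i = ilo + r
        if L == LAYER_D:
            f = code & 7
            if f == 5:
                if r != 0:
                    raise AssertionError("start reached above row 0")
                break
            if f in (1, 2, 3):
                moves.append(("D", i, j))
                L = {1: LAYER_D, 2: LAYER_H, 3: LAYER_V}[f]
                r -= 1
                c -= 3
            elif f == 4:
                info = int(dclose[r * (w + 1) + c])
                jd = info >> 3
                p = (info >> 1) & 3
                bl = info & 1
                ja = j - 3 + p
                moves.append(("I", i, jd, ja, p))
                L = LAYER_D if bl == 0 else LAYER_H
                r -= 1
                c = (jd - p) - jlo
            else:
                raise AssertionError(f"invalid D traceback at ({r},{c})")
        elif L == LAYER_V:
            f = (code >> 3) & 3
            if f == 3:
                if r != 0 or c != 0:
                    raise AssertionError("pinned V start mismatch")
                break
            if f == 0:
                raise AssertionError(f"invalid V traceback at ({r},{c})")
            moves.append(("V", i, j))
            L = LAYER_D if f == 1 else LAYER_V
            r -= 1
        else:  # LAYER_H
            f = (code >> 5) & 7
            if f == 4:
                break
            if f == 1:
                moves.append(("H", i, j))
                L = LAYER_D
                c -= 3
            elif f == 2:
                moves.append(("H", i, j))
                L = LAYER_H
                c -= 3
            elif f == 3:
                jd = int(hiclose[r * (w + 1) + c])
                ja = j - 3
                moves.append(("HI", i, jd, ja))
                L = LAYER_H
                c = jd - jlo
            else:
                raise AssertionError(f"invalid H traceback at ({r},{c})")
    moves.reverse()
    return moves, jlo + c


def _run_fill(ctx: SegmentContext, q: np.ndarray, ilo: int, jlo: int, jhi: int,
              start_layer: int, end_layer: int, end_j: int, band_w: int):
    """Allocate traceback, run the fill kernel, and walk the path."""
    mrows = len(q)
    w = jhi - jlo
    tb = np.zeros((mrows + 1, w + 1), dtype=np.uint16)
    wlo = np.zeros(mrows + 1, dtype=np.int64)
    whi = np.zeros(mrows + 1, dtype=np.int64)
    nbytes = 2 * (mrows + 1) * (w + 1)
    METER.alloc(nbytes)
    RECALC.add((mrows + 1) * (w + 1))
    score, end_c, end_l, dclose, hiclose = _kernel.fill_tb(
        q, ctx.nt, ctx.caa, CODON2AA,
        ctx.dpos, ctx.dcls, ctx.dsc, ctx.acls_arr, ctx.asc_arr,
        ctx.pen, ctx.subm,
        ctx.v, ctx.u, ctx.lmin,
        jlo, jhi,
        start_layer, end_layer, end_j,
        band_w,
        tb, wlo, whi,
    )
    if score <= NEG_HALF:
        METER.free(nbytes)
        return None
    moves, start_j = _walk_tb(tb, dclose, hiclose, ilo, jlo, w, mrows, end_c, end_l)
    METER.free(nbytes)
    return int(score), moves, start_j, jlo + end_c, end_l, (wlo, whi)


# ---------------------------------------------------------------------------
# Public alignment operations
# ---------------------------------------------------------------------------

def _check_inputs(query, segment) -> None:
    qlen = len(query.residues if isinstance(query, SequenceRecord) else str(query))
    if qlen < 1:
        raise ContractViolation("query must contain at least one residue")
    if isinstance(segment, SegmentContext):
        seg_len = segment.n
    else:
        seg_len = len(segment.residues if isinstance(segment, SequenceRecord)
                      else str(segment))
    if seg_len < 3:
        raise ContractViolation("genomic segment must span at least one codon")


def align_full(query: SequenceRecord, segment, params: SpeciesParams,
               config: RunConfig | None = None):
    """Optimal semi-global spliced alignment by full-matrix DP.

    Returns ``(score, GeneModel)``; the model is None when no path reaches
    the configured minimum report score.
    """
    config = config or RunConfig(min_report_score=0)
    _check_inputs(query, segment)
    ctx = segment if isinstance(segment, SegmentContext) else \
        SegmentContext.build(segment, params)
    q = encode_protein(query.residues if isinstance(query, SequenceRecord)
                       else str(query))
    res = _run_fill(ctx, q, 0, 0, ctx.n, -1, -1, 0, 0)
    if res is None:
        return NEG, None
    score, moves, start_j, _ej, _el, _win = res
    qrec = query if isinstance(query, SequenceRecord) else SequenceRecord("q", str(query))
    model = _moves_to_model(moves, qrec, ctx, score, start_j)
    audit = model.recompute_score(qrec.residues, ctx)
    if audit != score:
        raise AssertionError(f"score audit failed: DP {score} != components {audit}")
    if score < config.min_report_score:
        return score, None
    return score, model


def align_banded(query: SequenceRecord, segment, params: SpeciesParams,
                 config: RunConfig | None = None, band_width: int | None = None):
    """Banded variant: each row's dense recurrence is restricted to a window
    of ``band_width`` codons around an adaptively tracked centre; intron
    closes are evaluated at any landing column so introns bypass the band
    by jump moves.  Equals :func:`align_full` whenever the unrestricted
    optimal path stays inside the moving window; a path touching the window
    edge sets ``GeneModel.truncated``.
    """
    config = config or RunConfig(min_report_score=0)
    bw = band_width if band_width is not None else config.band_width
    if bw < 1:
        raise ContractViolation("band width must be >= 1 codon")
    _check_inputs(query, segment)
    ctx = segment if isinstance(segment, SegmentContext) else \
        SegmentContext.build(segment, params)
    q = encode_protein(query.residues if isinstance(query, SequenceRecord)
                       else str(query))
    res = _run_fill(ctx, q, 0, 0, ctx.n, -1, -1, 0, 3 * bw + 2)
    if res is None:
        return NEG, None
    score, moves, start_j, _ej, _el, (wlo, whi) = res
    qrec = query if isinstance(query, SequenceRecord) else SequenceRecord("q", str(query))
    # truncation check: did the chosen path touch a window edge?
    truncated = False
    for mv in moves:
        if mv[0] in ("D", "V", "H"):
            r = mv[1]
            c = mv[2] if mv[0] != "V" else mv[2]
            cc = c - 0
            if wlo[r] > 0 and cc <= wlo[r]:
                truncated = True
            if whi[r] < ctx.n and cc >= whi[r]:
                truncated = True
    model = _moves_to_model(moves, qrec, ctx, score, start_j, truncated=truncated)
    audit = model.recompute_score(qrec.residues, ctx)
    if audit != score:
        raise AssertionError(f"score audit failed: DP {score} != components {audit}")
    if score < config.min_report_score:
        return score, None
    return score, model


@dataclass
class LinkArrays:
    """Vertical/horizontal link arrays of one forward scan.

    ``VL[c][p][j]`` is the genomic coordinate at which the optimal path to
    the cell on intermediate ``c+1`` (0-indexed here) in layer p (0 =
    diagonal, 1 = vertical) crossed the previous intermediate; for the
    first intermediate it is the coordinate at which the alignment starts.
    ``HL`` carries horizontal provenance: gap origins, and donor
    coordinates where the crossing sits at an intron.  4-byte integers:
    storage is 16*k*n bytes total for both arrays.
    """

    intermediates: np.ndarray
    VL_enc: np.ndarray
    HL: np.ndarray
    wdict: dict
    jlo: int = 0

    @property
    def k(self) -> int:
        return len(self.intermediates)

    @property
    def VL(self) -> np.ndarray:
        out = self.VL_enc.copy()
        valid = out >= 0
        out[valid] >>= 1
        return out

    @property
    def nbytes(self) -> int:
        return self.VL_enc.nbytes + self.HL.nbytes


def forward_scan(query: SequenceRecord, segment, params: SpeciesParams,
                 config: RunConfig | None = None, links: int | None = None):
    """Score-only forward pass in O(n) memory per layer.

    ``links``: number of intermediates k (or None for a pure score pass).
    Returns ``(score, (m, j_end, layer), LinkArrays|None)`` under the
    semi-global end rule.
    """
    _check_inputs(query, segment)
    ctx = segment if isinstance(segment, SegmentContext) else \
        SegmentContext.build(segment, params)
    q = encode_protein(query.residues if isinstance(query, SequenceRecord)
                       else str(query))
    m = len(q)
    k = int(links) if links else 0
    inter = np.array([(c * m) // (k + 1) for c in range(1, k + 1)], dtype=np.int64)
    inter = np.unique(inter[(inter > 0) & (inter < m)])
    score, end_c, end_l, links_obj = _scan(ctx, q, 0, 0, ctx.n, -1, -1, 0, inter)
    return int(score), (m, end_c, end_l), links_obj


def _scan(ctx: SegmentContext, q: np.ndarray, ilo: int, jlo: int, jhi: int,
          start_layer: int, end_layer: int, end_j: int, inter: np.ndarray):
    """Run the link-carrying forward kernel over a rectangle."""
    w = jhi - jlo
    k = len(inter)
    VL_enc = np.full((max(k, 1), 2, w + 1), -1, dtype=np.int64)
    HL = np.full((max(k, 1), 2, w + 1), -1, dtype=np.int64)
    from numba import types as _t
    from numba.typed import Dict as _Dict
    wdict = _Dict.empty(_t.int64, _t.int64)
    nbytes = 16 * k * (w + 1)
    METER.alloc(nbytes)
    score, end_c, end_l, ew0, ew1, ew2 = _kernel.scan_links(
        q, ctx.nt, ctx.caa, CODON2AA,
        ctx.dpos, ctx.dcls, ctx.dsc, ctx.acls_arr, ctx.asc_arr,
        ctx.pen, ctx.subm,
        ctx.v, ctx.u, ctx.lmin,
        jlo, jhi,
        start_layer, end_layer, end_j,
        inter,
        VL_enc, HL, wdict,
    )
    links_obj = LinkArrays(inter, VL_enc, HL, wdict, jlo)
    links_obj._end = (int(score), jlo + int(end_c), int(end_l),
                      int(ew0), int(ew1), int(ew2))
    links_obj._meter_bytes = nbytes
    return int(score), jlo + int(end_c), int(end_l), links_obj
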