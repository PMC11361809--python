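"""Linear-space traceback: unidirectional Hirschberg methods.

The score-only forward pass needs O(n) state per layer, so the memory
problem is the traceback.  Two remedies are combined:

* **SIUDH** (single-intermediate unidirectional Hirschberg): one forward
  pass carries, for every cell, the coordinate at which its best path
  crosses the middle row; the problem splits there and recursion stops as
  soon as a subproblem's two-byte-per-cell traceback fits the budget
  ``V_max``.
* **MIUDH** (multi-intermediate): one forward pass carries crossing
  coordinates for k intermediate rows i_c = floor(c*m/(k+1)) in the
  vertical/horizontal link arrays; the k+1 sub-rectangles delimited by the
  recorded crossings are then re-aligned with the full-matrix kernel and
  concatenated.  With 4-byte link entries and 2-byte traceback cells the
  expected memory is

      M(k, m, n) = 16*n*k + 2*m*n*(k+1)^-2   bytes,

  minimised near k-hat(m) = (m/4)^(1/3) - 1.

When a crossing lands where the path sits in an intron or inside a
horizontal gap, the link arrays' horizontal words resolve the donor
coordinate so the recalculation treats the intron as a single jump and
never refills its interior — the sub-rectangles shrink accordingly.

By default the two methods are chosen automatically: MIUDH whenever
M(k-hat(m'), m', n') fits V_max, otherwise a SIUDH split whose subproblems
re-enter the same decision.  All three drivers reproduce the full-matrix
alignment exactly (same score, same gene model) thanks to the shared
deterministic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernel import LAYER_D, LAYER_V, NEG, NEG_HALF
from .dp import (
    METER,
    RECALC,
    ContractViolation,
    SegmentContext,
    _moves_to_model,
    _run_fill,
    _scan,
    align_full,
)
from .scoring import SpeciesParams, encode_protein
from .seqio import RunConfig, SequenceRecord


# ---------------------------------------------------------------------------
# Memory model
# ---------------------------------------------------------------------------

def memory_estimate(k: int, m: int, n: int) -> float:
    """Approximate traceback memory M(k, m, n) = 16nk + 2mn(k+1)^-2 bytes.

    k = 0 degenerates to the plain full-traceback cost 2mn.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    return 16.0 * n * k + 2.0 * m * n / (k + 1) ** 2


def choose_k(m: int) -> tuple[float, int]:
    """Continuous and integer optimal intermediate counts for query length m.

    The continuous minimiser of M is k-hat(m) = (m/4)^(1/3) - 1 (n factors
    out).  The integer k is whichever of floor/ceil of k-hat gives the
    smaller M, floored at 1 for MIUDH use; k-hat itself may be <= 0 for
    tiny m, in which case plain full-matrix traceback is the right regime.
    """
    if m < 1:
        raise ValueError("query length must be positive")
    khat = (m / 4.0) ** (1.0 / 3.0) - 1.0
    lo = max(1, int(np.floor(khat)))
    hi = max(1, int(np.ceil(khat)))
    k = lo if memory_estimate(lo, m, 1) <= memory_estimate(hi, m, 1) else hi
    return khat, k


@dataclass
class MIUDHPlan:
    """Record of the algorithm-selection decision path."""

    algorithm: str                      # miudh | siudh-recursive | fullmatrix
    k: int = 0
    intermediates: list[int] = field(default_factory=list)
    v_max: int = 0
    decisions: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Single-row travel reconstruction (crossing inside a gap/intron)
# ---------------------------------------------------------------------------

def _row_travel(ctx: SegmentContext, row_abs: int, j_from: int, j_to: int,
                base_layer: int) -> list[tuple]:
    """Reconstruct the horizontal travel along one row from the arrival
    cell (j_from, D) to the intron-open base cell (j_to, base_layer).

    The travel consists of H moves, possibly interrupted by introns inside
    the deletion (HI).  A D base means no travel at all.
    """
    if base_layer == 0:
        if j_to != j_from:
            raise AssertionError("D-layer intron base away from the arrival cell")
        return []
    if j_to <= j_from:
        raise AssertionError("empty horizontal travel to an H-layer base")
    RECALC.add(j_to - j_from + 1)
    v, u, lmin = ctx.v, ctx.u, ctx.lmin
    H: dict[int, int] = {}
    bp: dict[int, tuple] = {}
    pend: list[tuple[int, int, int]] = []  # (j_donor, value, class01)
    dset = {int(p): (int(c), int(s))
            for p, c, s in zip(ctx.dpos, ctx.dcls, ctx.dsc)
            if j_from < p <= j_to}
    for j in range(j_from + 1, j_to + 1):
        best = NEG
        move: tuple = ()
        if j - 3 >= j_from:
            if j - 3 == j_from:
                cand = -v - u
                if cand > best:
                    best, move = cand, ("open",)
            if (j - 3) in H and H[j - 3] - u > best:
                best, move = H[j - 3] - u, ("ext",)
            ja = j - 3
            if ja - 2 > j_from and ctx.acls_arr[ja] >= 0:
                acls = int(ctx.acls_arr[ja])
                asc = int(ctx.asc_arr[ja])
                for jd, val, cls in pend:
                    if cls != acls or jd > ja - lmin:
                        continue
                    cand = val + asc - int(ctx.pen[ja - jd]) - u
                    if cand > best:
                        best, move = cand, ("hi", jd, ja)
        if best > NEG_HALF:
            H[j] = best
            bp[j] = move
            if j in dset and j + 2 <= j_to + (1 << 30):
                cls, dsc = dset[j]
                pend.append((j, best + dsc, 0 if cls <= 1 else 1))
    if j_to not in H:
        raise AssertionError("horizontal travel reconstruction failed")
    moves: list[tuple] = []
    j = j_to
    while True:
        mv = bp[j]
        if mv[0] == "open":
            moves.append(("H", row_abs, j))
            break
        if mv[0] == "ext":
            moves.append(("H", row_abs, j))
            j -= 3
        else:
            _, jd, ja = mv
            moves.append(("HI", row_abs, jd, ja))
            j = jd
    moves.reverse()
    return moves


# ---------------------------------------------------------------------------
# MIUDH reconstruction
# ---------------------------------------------------------------------------

def _solve_rect(ctx, q, ilo, ihi, jlo, jhi, start_layer, end_layer, end_j):
    """Pinned full-matrix fill over one sub-rectangle; returns moves."""
    res = _run_fill(ctx, q[ilo:ihi], ilo, jlo, jhi, start_layer, end_layer,
                    end_j, 0)
    if res is None:
        raise AssertionError("pinned sub-rectangle has no valid path")
    _score, moves, _sj, _ej, _el, _win = res
    return moves


def _decode_wpair(links, ci, lb, jc):
    w = links.VL_enc.shape[2] - 1
    key = (ci * 2 + lb) * (w + 1) + (jc - links.jlo)
    if key in links.wdict:
        packed = int(links.wdict[key])
        return packed >> 31, packed & ((1 << 31) - 1)
    return -1, -1


def _miudh_moves(ctx, q, ilo, ihi, jlo, jhi, start_layer, end_layer, end_j,
                 k) -> tuple[int, list[tuple]]:
    """One link-carrying forward pass + k+1 pinned recalculations."""
    m = ihi - ilo
    inter = np.array(sorted({(c * m) // (k + 1) for c in range(1, k + 1)}),
                     dtype=np.int64)
    inter = inter[(inter > 0) & (inter < m)]
    if len(inter) == 0:
        res = _run_fill(ctx, q[ilo:ihi], ilo, jlo, jhi, start_layer,
                        end_layer, end_j, 0)
        if res is None:
            return NEG, []
        return res[0], res[1]
    score, endj_abs, endl, links = _scan(ctx, q[ilo:ihi], ilo, jlo, jhi,
                                         start_layer, end_layer, end_j, inter)
    if score <= NEG_HALF:
        METER.free(links._meter_bytes)
        return NEG, []
    _sc, _ej, _el, ew0, ew1, ew2 = links._end

    # walk crossings from the top intermediate down to the start cell
    segs = []
    up_row, up_j, up_l = m, endj_abs, endl
    w0, w1, w2 = ew0, ew1, ew2
    for ci in range(len(inter) - 1, -1, -1):
        jc, lb = w0 >> 1, w0 & 1
        segs.append((int(inter[ci]), jc, lb, w1, w2, up_row, up_j, up_l))
        up_row, up_j, up_l = int(inter[ci]), jc, lb
        w0 = int(links.VL_enc[ci, lb, jc - jlo])
        w1, w2 = _decode_wpair(links, ci, lb, jc)
    jc, lb = w0 >> 1, w0 & 1  # the start cell (row 0 of this rectangle)
    segs.append((0, jc, lb, -1, -1, up_row, up_j, up_l))

    all_moves: list[tuple] = []
    for low_row, low_j, low_lb, jw1, jw2, hi_row, hi_j, hi_l in reversed(segs):
        low_layer = LAYER_D if low_lb == 0 else LAYER_V
        hi_layer = hi_l if hi_row == m and end_layer >= 0 else hi_l
        if jw1 >= 0:
            j_land = jw1 >> 1
            jd = jw2 >> 3
            p = (jw2 >> 1) & 3
            bl = jw2 & 1
            ja = j_land - (3 - p)
            travel = _row_travel(ctx, ilo + low_row, low_j, jd - p, bl)
            all_moves.extend(travel)
            all_moves.append(("I", ilo + low_row + 1, jd, ja, p))
            if low_row + 1 == hi_row:
                if j_land != hi_j or hi_l != LAYER_D:
                    raise AssertionError("jump landing does not match crossing")
            else:
                all_moves.extend(
                    _solve_rect(ctx, q, ilo + low_row + 1, ilo + hi_row,
                                j_land, hi_j, LAYER_D, hi_l, hi_j)
                )
        else:
            all_moves.extend(
                _solve_rect(ctx, q, ilo + low_row, ilo + hi_row,
                            low_j, hi_j, low_layer, hi_l, hi_j)
            )
    METER.free(links._meter_bytes)
    return int(score), all_moves


# ---------------------------------------------------------------------------
# SIUDH recursion
# ---------------------------------------------------------------------------

def _siudh_moves(ctx, q, ilo, ihi, jlo, jhi, start_layer, end_layer, end_j,
                 v_max, hybrid, plan) -> tuple[int, list[tuple]]:
    m = ihi - ilo
    n = jhi - jlo
    if m < 2 or 2 * m * n <= v_max:
        plan.decisions.append(f"leaf fullmatrix m'={m} n'={n}")
        res = _run_fill(ctx, q[ilo:ihi], ilo, jlo, jhi, start_layer,
                        end_layer, end_j, 0)
        if res is None:
            return NEG, []
        return res[0], res[1]
    if hybrid:
        khat, kint = choose_k(m)
        if khat > 0 and memory_estimate(khat, m, n) < v_max:
            plan.decisions.append(f"miudh k={kint} m'={m} n'={n}")
            return _miudh_moves(ctx, q, ilo, ihi, jlo, jhi, start_layer,
                                end_layer, end_j, kint)
    plan.decisions.append(f"siudh split m'={m} n'={n}")
    mid = m // 2
    inter = np.array([mid], dtype=np.int64)
    score, endj_abs, endl, links = _scan(ctx, q[ilo:ihi], ilo, jlo, jhi,
                                         start_layer, end_layer, end_j, inter)
    if score <= NEG_HALF:
        METER.free(links._meter_bytes)
        return NEG, []
    _sc, _ej, _el, ew0, ew1, ew2 = links._end
    METER.free(links._meter_bytes)
    jc, lb = ew0 >> 1, ew0 & 1
    low_layer = LAYER_D if lb == 0 else LAYER_V
    moves: list[tuple] = []
    if ew1 >= 0:
        j_land = ew1 >> 1
        jd = ew2 >> 3
        p = (ew2 >> 1) & 3
        bl = ew2 & 1
        ja = j_land - (3 - p)
        s_low, mv_low = _siudh_moves(ctx, q, ilo, ilo + mid, jlo, jc,
                                     start_layer, low_layer, jc, v_max,
                                     hybrid, plan)
        moves.extend(mv_low)
        moves.extend(_row_travel(ctx, ilo + mid, jc, jd - p, bl))
        moves.append(("I", ilo + mid + 1, jd, ja, p))
        if ilo + mid + 1 == ihi:
            if j_land != endj_abs or endl != LAYER_D:
                raise AssertionError("jump landing does not match end cell")
        else:
            _s, mv_up = _siudh_moves(ctx, q, ilo + mid + 1, ihi, j_land,
                                     endj_abs, LAYER_D, endl, endj_abs,
                                     v_max, hybrid, plan)
            moves.extend(mv_up)
    else:
        _s, mv_low = _siudh_moves(ctx, q, ilo, ilo + mid, jlo, jc,
                                  start_layer, low_layer, jc, v_max,
                                  hybrid, plan)
        moves.extend(mv_low)
        _s, mv_up = _siudh_moves(ctx, q, ilo + mid, ihi, jc, endj_abs,
                                 low_layer, endl, endj_abs, v_max,
                                 hybrid, plan)
        moves.extend(mv_up)
    return int(score), moves


# ---------------------------------------------------------------------------
# Public drivers
# ---------------------------------------------------------------------------

def _finish(query, ctx, config, score, moves):
    if score <= NEG_HALF:
        return NEG, None
    start_j = _moves_start(moves)
    model = _moves_to_model(moves, query, ctx, score, start_j)
    audit = model.recompute_score(query.residues, ctx)
    if audit != score:
        raise AssertionError(f"score audit failed: DP {score} != components {audit}")
    if score < config.min_report_score:
        return score, None
    return score, model


def _moves_start(moves) -> int:
    for mv in moves:
        if mv[0] == "D":
            return mv[2] - 3
        if mv[0] == "H":
            return mv[2] - 3
        if mv[0] == "I":
            return mv[2] - mv[4]  # donor minus phase
        if mv[0] == "HI":
            return mv[2] - 3
    return 0


def _prep(query, segment, params):
    ctx = segment if isinstance(segment, SegmentContext) else \
        SegmentContext.build(segment, params)
    qrec = query if isinstance(query, SequenceRecord) else \
        SequenceRecord("q", str(query))
    if len(qrec) < 1:
        raise ContractViolation("query must contain at least one residue")
    if ctx.n < 3:
        raise ContractViolation("genomic segment must span at least one codon")
    return ctx, qrec, encode_protein(qrec.residues)


def align_miudh(query, segment, params: SpeciesParams,
                config: RunConfig | None = None, k: int | None = None):
    """Multi-intermediate Hirschberg alignment, identical to align_full."""
    config = config or RunConfig(min_report_score=0)
    ctx, qrec, q = _prep(query, segment, params)
    if k is None:
        k = choose_k(len(q))[1]
    if k < 1:
        raise ContractViolation("MIUDH needs k >= 1")
    score, moves = _miudh_moves(ctx, q, 0, len(q), 0, ctx.n, -1, -1, 0, k)
    return _finish(qrec, ctx, config, score, moves)


def align_siudh(query, segment, params: SpeciesParams,
                config: RunConfig | None = None):
    """Recursive single-intermediate Hirschberg, identical to align_full."""
    config = config or RunConfig(min_report_score=0)
    ctx, qrec, q = _prep(query, segment, params)
    plan = MIUDHPlan("siudh-recursive", v_max=config.v_max)
    score, moves = _siudh_moves(ctx, q, 0, len(q), 0, ctx.n, -1, -1, 0,
                                config.v_max, False, plan)
    return _finish(qrec, ctx, config, score, moves)


def align_auto(query, segment, params: SpeciesParams,
               config: RunConfig | None = None):
    """Hybrid strategy under the V_max memory budget.

    Full-matrix when the whole traceback fits (2mn <= V_max); MIUDH with
    the optimal k when M(k-hat, m, n) fits; otherwise recursive SIUDH
    whose leaf subproblems re-enter this decision.  Returns
    ``(score, model, plan)``.
    """
    config = config or RunConfig(min_report_score=0)
    ctx, qrec, q = _prep(query, segment, params)
    m, n = len(q), ctx.n
    v_max = config.v_max
    if 2 * m * n <= v_max:
        plan = MIUDHPlan("fullmatrix", v_max=v_max,
                         decisions=[f"fullmatrix 2mn={2 * m * n} <= V_max"])
        score, model = align_full(qrec, ctx, params, config)
        return score, model, plan
    khat, kint = choose_k(m)
    if khat > 0 and memory_estimate(khat, m, n) < v_max:
        inter = [(c * m) // (kint + 1) for c in range(1, kint + 1)]
        plan = MIUDHPlan("miudh", k=kint, intermediates=inter, v_max=v_max,
                         decisions=[f"miudh M(k-hat)={memory_estimate(khat, m, n):.0f} < V_max"])
        score, moves = _miudh_moves(ctx, q, 0, m, 0, n, -1, -1, 0, kint)
        score, model = _finish(qrec, ctx, config, score, moves)
        return score, model, plan
    plan = MIUDHPlan("siudh-recursive", v_max=v_max,
                     decisions=[f"siudh M(k-hat)={memory_estimate(max(khat, 0), m, n):.0f} >= V_max"])
    score, moves = _siudh_moves(ctx, q, 0, m, 0, n, -1, -1, 0, v_max, True, plan)
    score, model = _finish(qrec, ctx, config, score, moves)
    return score, model, plan
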