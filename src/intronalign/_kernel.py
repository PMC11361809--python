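"""Numba kernels for the spliced-alignment recurrences.

Two kernels share one move grammar and one deterministic tie-breaking order:

``fill_tb``
    Fills the DP matrix over a (row, column) rectangle with a packed
    two-byte traceback word per cell, supporting free (semi-global) or
    pinned boundaries and an optional adaptively centred band.

``scan_links``
    Score-only forward pass in O(n) rows of state, propagating the
    vertical/horizontal link coordinates through every MAX operation and
    snapshotting them at k intermediate rows, which is what the
    single-/multi-intermediate unidirectional Hirschberg drivers consume.

Layers: D=0 (diagonal, one residue vs one codon), V=1 (unpaired residue),
H=2 (unpaired in-frame codon).  Intron states are not materialised per
cell; each row transition keeps per-(phase, acceptor-class, partial-codon)
Pareto lists of pending donors, pruned by the rule that a donor is
dominated by a later donor with an equal-or-better entry score (valid
because every penalty mode is non-decreasing in intron length).  A
separate pending channel (HI) realises a deletion striding across an
intron: it is opened from H and closes back into H on the same row with
no second gap-open charge.

Tie-breaking everywhere: diagonal-from-D > diagonal-from-H >
diagonal-from-V > intron closes (lower phase first, then later donor);
end cells prefer D > H > V and then the smaller column.  Both kernels
apply the same order, which makes the linear-space drivers reproduce the
full-matrix alignment exactly, not just its score.
"""

import numpy as np
from numba import njit, types
from numba.typed import Dict

NEG = -(1 << 29)
NEG_HALF = -(1 << 28)

LAYER_D, LAYER_V, LAYER_H = 0, 1, 2

# traceback word fields
#   bits 0-2  D move: 1 from D, 2 from H, 3 from V, 4 intron close, 5 start
#   bits 3-4  V move: 1 from D, 2 from V, 3 start
#   bits 5-7  H move: 1 open from D, 2 extend, 3 HI close, 4 start

I64 = types.int64


@njit(cache=True)
def _stack_id(cls01, p, code):
    # per-class stack offsets: p=0 -> 0, p=1 -> 1+code (5), p=2 -> 6+code (25)
    if p == 0:
        return cls01 * 31
    elif p == 1:
        return cls01 * 31 + 1 + code
    else:
        return cls01 * 31 + 6 + code


@njit(cache=True)
def _bridged_aa(code, p, nt, ja, codon2aa):
    """Amino-acid column of the codon bridged by a phase-p intron."""
    # leading p nucleotides encoded base-5 in `code`, trailing 3-p start at ja
    n0 = np.int64(-1)
    n1 = np.int64(-1)
    n2 = np.int64(-1)
    if p == 1:
        n0 = np.int64(code)
        n1 = np.int64(nt[ja])
        n2 = np.int64(nt[ja + 1])
    elif p == 2:
        n0 = np.int64(code // 5)
        n1 = np.int64(code % 5)
        n2 = np.int64(nt[ja])
    else:
        n0 = np.int64(nt[ja])
        n1 = np.int64(nt[ja + 1])
        n2 = np.int64(nt[ja + 2])
    if n0 == 4 or n1 == 4 or n2 == 4:
        return np.int64(20)  # any N -> X
    return np.int64(codon2aa[16 * n0 + 4 * n1 + n2])


@njit(cache=True)
def fill_tb(qs, nt, caa, codon2aa,
            dpos, dcls, dsc, acls_arr, asc_arr, pen, subm,
            v, u, lmin,
            jlo, jhi,
            start_layer, end_layer, end_j,
            band_w,
            tb, wlo_out, whi_out):
    """Rectangle fill with traceback.

    Rows 0..mrows cover query residues qs[0..mrows-1]; columns are the
    absolute genomic positions jlo..jhi.  ``start_layer`` -1 means a free
    semi-global start (row 0 of layer D is 0 everywhere); 0/1 pin layer
    D/V to column jlo.  ``end_layer`` -1 selects the best semi-global end
    on the last row; otherwise the end is pinned to (end_j, end_layer).
    ``band_w`` > 0 restricts the dense recurrence of each row to a window
    of that nucleotide half-width around an adaptively tracked centre
    (intron closes are still evaluated at any landing column).

    Returns (score, end_c, end_l, dclose, hiclose).
    """
    mrows = qs.shape[0]
    w = jhi - jlo  # local columns 0..w
    ndon = dpos.shape[0]

    dclose = Dict.empty(I64, I64)
    hiclose = Dict.empty(I64, I64)

    Dp = np.full(w + 1, NEG, dtype=np.int64)
    Vp = np.full(w + 1, NEG, dtype=np.int64)
    Hp = np.full(w + 1, NEG, dtype=np.int64)
    Dc = np.full(w + 1, NEG, dtype=np.int64)
    Vc = np.full(w + 1, NEG, dtype=np.int64)
    Hc = np.full(w + 1, NEG, dtype=np.int64)

    # pending-donor Pareto stacks for D closes (62 = 2 classes x 31 offsets)
    cap = ndon + 1
    st_j = np.empty((62, cap), dtype=np.int64)
    st_val = np.empty((62, cap), dtype=np.int64)
    st_bl = np.empty((62, cap), dtype=np.int8)
    st_n = np.zeros(62, dtype=np.int64)
    # HI pendings (2 classes)
    hi_j = np.empty((2, cap), dtype=np.int64)
    hi_val = np.empty((2, cap), dtype=np.int64)
    hi_n = np.zeros(2, dtype=np.int64)

    # first donor index relevant to this rectangle
    d0 = 0
    while d0 < ndon and dpos[d0] < jlo:
        d0 += 1

    # ---- row 0 -----------------------------------------------------------
    if start_layer < 0:
        for c in range(w + 1):
            Dc[c] = 0
            tb[0, c] = 5  # D start
    else:
        if start_layer == LAYER_D:
            Dc[0] = 0
            tb[0, 0] = 5
        else:  # pinned V
            Vc[0] = 0
            tb[0, 0] = 3 << 3

    center = jlo  # band centre (absolute)

    for r in range(0, mrows + 1):
        if r > 0:
            # roll rows
            Dp[:] = Dc
            Vp[:] = Vc
            Hp[:] = Hc
            Dc[:] = NEG
            Vc[:] = NEG
            Hc[:] = NEG
            st_n[:] = 0
        for s in range(2):
            hi_n[s] = 0

        # dense window for this row
        if band_w > 0:
            lo = center - band_w - jlo
            hi = center + band_w - jlo
            if lo < 0:
                lo = 0
            if hi > w:
                hi = w
            if r == 0 and start_layer < 0:
                lo = 0
                hi = w
        else:
            lo = 0
            hi = w
        wlo_out[r] = lo
        whi_out[r] = hi

        qres = np.int64(0)
        if r > 0:
            qres = np.int64(qs[r - 1])

        dptr0 = d0
        dptr1 = d0
        dptr2 = d0
        hptr = d0

        best_row = NEG
        best_c = 0

        for c in range(0, w + 1):
            j = jlo + c

            # ---------- D layer (only for r >= 1) -------------------------
            if r >= 1:
                bestD = NEG
                mvD = np.int64(0)
                if c >= 3 and caa[j] >= 0:
                    sub = np.int64(subm[qres, caa[j]])
                    cand = Dp[c - 3] + sub
                    if cand > bestD:
                        bestD = cand
                        mvD = 1
                    cand = Hp[c - 3] + sub
                    if cand > bestD:
                        bestD = cand
                        mvD = 2
                    cand = Vp[c - 3] + sub
                    if cand > bestD:
                        bestD = cand
                        mvD = 3
                # intron closes, phases 0..2 (acceptor ends at ja = j-3+p)
                for p in range(3):
                    ja = j - 3 + p
                    if ja - 2 < jlo or ja < jlo:
                        continue
                    if ja + (3 - p) > jhi:
                        continue
                    # lazily insert donors eligible for this phase
                    if p == 0:
                        dp = dptr0
                    elif p == 1:
                        dp = dptr1
                    else:
                        dp = dptr2
                    while dp < ndon and dpos[dp] <= ja - lmin:
                        jd = dpos[dp]
                        bcol = jd - p - jlo
                        if bcol >= 0 and jd + 2 <= jhi:
                            bval = Dp[bcol]
                            bl = np.int8(0)
                            if Hp[bcol] > bval:
                                bval = Hp[bcol]
                                bl = np.int8(1)
                            if bval > NEG_HALF:
                                code = np.int64(0)
                                ok = True
                                if p == 1:
                                    code = np.int64(nt[jd - 1])
                                elif p == 2:
                                    code = np.int64(nt[jd - 2]) * 5 + np.int64(nt[jd - 1])
                                cls01 = 0 if dcls[dp] <= 1 else 1
                                val = bval + np.int64(dsc[dp])
                                sid = _stack_id(cls01, p, code)
                                nstk = st_n[sid]
                                while nstk > 0 and st_val[sid, nstk - 1] <= val:
                                    nstk -= 1
                                st_j[sid, nstk] = jd
                                st_val[sid, nstk] = val
                                st_bl[sid, nstk] = bl
                                st_n[sid] = nstk + 1
                        dp += 1
                    if p == 0:
                        dptr0 = dp
                    elif p == 1:
                        dptr1 = dp
                    else:
                        dptr2 = dp
                    acls = np.int64(acls_arr[ja])
                    if acls < 0:
                        continue
                    asc = np.int64(asc_arr[ja])
                    ncodes = 1 if p == 0 else (5 if p == 1 else 25)
                    for code in range(ncodes):
                        sid = _stack_id(acls, p, code)
                        nstk = st_n[sid]
                        if nstk == 0:
                            continue
                        aacol = _bridged_aa(code, p, nt, ja, codon2aa)
                        sub = np.int64(subm[qres, aacol])
                        beste = NEG
                        arge = -1
                        for e in range(nstk - 1, -1, -1):
                            candv = st_val[sid, e] - np.int64(pen[ja - st_j[sid, e]])
                            if candv > beste:
                                beste = candv
                                arge = e
                        total = beste + asc + sub
                        if total > bestD:
                            bestD = total
                            mvD = 4
                            key = np.int64(r) * (w + 1) + c
                            info = (st_j[sid, arge] << 3) | (np.int64(p) << 1) \
                                | np.int64(st_bl[sid, arge])
                            dclose[key] = info
                if bestD > NEG_HALF and (lo <= c <= hi or mvD == 4):
                    Dc[c] = bestD
                    tb[r, c] = (tb[r, c] & 0xFFF8) | mvD

                # ---------- V layer ---------------------------------------
                if lo <= c <= hi:
                    bestV = NEG
                    mvV = np.int64(0)
                    cand = Dp[c] - v - u
                    if cand > bestV:
                        bestV = cand
                        mvV = 1
                    cand = Vp[c] - u
                    if cand > bestV:
                        bestV = cand
                        mvV = 2
                    if bestV > NEG_HALF:
                        Vc[c] = bestV
                        tb[r, c] = (tb[r, c] & 0xFFE7) | (mvV << 3)

            # ---------- H layer (computed on all rows; band gates storage) -
            if True:
                # HI donor insertion: base H cells earlier in this row
                while hptr < ndon and dpos[hptr] <= (j - 3) - lmin:
                    jd = dpos[hptr]
                    bcol = jd - jlo
                    if bcol >= 0 and jd + 2 <= jhi and Hc[bcol] > NEG_HALF:
                        cls01 = 0 if dcls[hptr] <= 1 else 1
                        val = Hc[bcol] + np.int64(dsc[hptr])
                        nstk = hi_n[cls01]
                        while nstk > 0 and hi_val[cls01, nstk - 1] <= val:
                            nstk -= 1
                        hi_j[cls01, nstk] = jd
                        hi_val[cls01, nstk] = val
                        hi_n[cls01] = nstk + 1
                    hptr += 1
                bestH = NEG
                mvH = np.int64(0)
                if c >= 3:
                    cand = Dc[c - 3] - v - u
                    if cand > bestH:
                        bestH = cand
                        mvH = 1
                    cand = Hc[c - 3] - u
                    if cand > bestH:
                        bestH = cand
                        mvH = 2
                    ja = j - 3
                    if ja - 2 >= jlo:
                        acls = np.int64(acls_arr[ja])
                        if acls >= 0 and hi_n[acls] > 0:
                            asc = np.int64(asc_arr[ja])
                            beste = NEG
                            arge = -1
                            for e in range(hi_n[acls] - 1, -1, -1):
                                candv = hi_val[acls, e] - np.int64(pen[ja - hi_j[acls, e]])
                                if candv > beste:
                                    beste = candv
                                    arge = e
                            total = beste + asc - u
                            if total > bestH:
                                bestH = total
                                mvH = 3
                                key = np.int64(r) * (w + 1) + c
                                hiclose[key] = hi_j[acls, arge]
                if bestH > NEG_HALF and (lo <= c <= hi or mvH == 3):
                    Hc[c] = bestH
                    tb[r, c] = (tb[r, c] & 0xFF1F) | (mvH << 5)

            # track row best for band recentering
            if band_w > 0:
                bb = Dc[c]
                if Hc[c] > bb:
                    bb = Hc[c]
                if Vc[c] > bb:
                    bb = Vc[c]
                if bb > best_row:
                    best_row = bb
                    best_c = c

        if band_w > 0:
            if best_row > 0:
                center = jlo + best_c
            else:
                center = center + 3

    # ---- end cell --------------------------------------------------------
    if end_layer < 0:
        score = NEG
        end_c = 0
        end_l = LAYER_D
        for c in range(w + 1):
            if Dc[c] > score:
                score = Dc[c]
                end_c = c
                end_l = LAYER_D
            if Hc[c] > score:
                score = Hc[c]
                end_c = c
                end_l = LAYER_H
            if Vc[c] > score:
                score = Vc[c]
                end_c = c
                end_l = LAYER_V
    else:
        end_c = end_j - jlo
        end_l = end_layer
        if end_l == LAYER_D:
            score = Dc[end_c]
        elif end_l == LAYER_V:
            score = Vc[end_c]
        else:
            score = Hc[end_c]

    return score, end_c, end_l, dclose, hiclose


@njit(cache=True)
def scan_links(qs, nt, caa, codon2aa,
               dpos, dcls, dsc, acls_arr, asc_arr, pen, subm,
               v, u, lmin,
               jlo, jhi,
               start_layer, end_layer, end_j,
               inter,
               VL_enc, HL, wdict):
    """Score-only forward pass carrying link coordinates.

    ``inter`` holds the k intermediate row indices (strictly increasing,
    inside (0, mrows)).  Each layer value carries three link words:

    * w0: encoded arrival cell ``(j << 1) | layerbit`` on the most recent
      intermediate row below (or the start cell before the first one);
    * w1/w2: if the path's departure from that intermediate row was an
      intron jump, the packed landing ``(j_land << 1) | 1`` and donor
      record ``(j_donor << 3) | (phase << 1) | base_layer``; else -1.

    At each intermediate row c the D/V links are snapshotted into
    ``VL_enc[c]`` (and their jump words into ``wdict``), gap/intron
    provenance into ``HL[c]``, and the carried links are refreshed: D and
    V cells to their own identity, H cells to their gap origin.

    Returns (score, end_c, end_l, ew0, ew1, ew2).
    """
    mrows = qs.shape[0]
    w = jhi - jlo
    ndon = dpos.shape[0]
    k = inter.shape[0]

    Dp = np.full(w + 1, NEG, dtype=np.int64)
    Vp = np.full(w + 1, NEG, dtype=np.int64)
    Hp = np.full(w + 1, NEG, dtype=np.int64)
    Dc = np.full(w + 1, NEG, dtype=np.int64)
    Vc = np.full(w + 1, NEG, dtype=np.int64)
    Hc = np.full(w + 1, NEG, dtype=np.int64)

    # link words per layer (prev and current row)
    lDp = np.full((3, w + 1), -1, dtype=np.int64)
    lVp = np.full((3, w + 1), -1, dtype=np.int64)
    lHp = np.full((3, w + 1), -1, dtype=np.int64)
    lDc = np.full((3, w + 1), -1, dtype=np.int64)
    lVc = np.full((3, w + 1), -1, dtype=np.int64)
    lHc = np.full((3, w + 1), -1, dtype=np.int64)
    hstart = np.full(w + 1, -1, dtype=np.int64)   # gap origin (absolute j)
    hi_donor = np.full(w + 1, -1, dtype=np.int64)  # case (e) landing -> donor

    cap = ndon + 1
    st_j = np.empty((62, cap), dtype=np.int64)
    st_val = np.empty((62, cap), dtype=np.int64)
    st_bl = np.empty((62, cap), dtype=np.int8)
    st_w = np.empty((3, 62, cap), dtype=np.int64)
    st_n = np.zeros(62, dtype=np.int64)
    hi_jd = np.empty((2, cap), dtype=np.int64)
    hi_val = np.empty((2, cap), dtype=np.int64)
    hi_hs = np.empty((2, cap), dtype=np.int64)
    hi_w = np.empty((3, 2, cap), dtype=np.int64)
    hi_n = np.zeros(2, dtype=np.int64)

    d0 = 0
    while d0 < ndon and dpos[d0] < jlo:
        d0 += 1

    if start_layer < 0:
        for c in range(w + 1):
            Dc[c] = 0
            lDc[0, c] = ((jlo + c) << 1) | 0
    else:
        if start_layer == LAYER_D:
            Dc[0] = 0
            lDc[0, 0] = (jlo << 1) | 0
        else:
            Vc[0] = 0
            lVc[0, 0] = (jlo << 1) | 1

    prev_inter_c = -1  # index of intermediate at row r-1 (or -1)
    next_ic = 0        # next intermediate to snapshot

    for r in range(0, mrows + 1):
        if r > 0:
            Dp[:] = Dc
            Vp[:] = Vc
            Hp[:] = Hc
            Dc[:] = NEG
            Vc[:] = NEG
            Hc[:] = NEG
            lDp[:, :] = lDc
            lVp[:, :] = lVc
            lHp[:, :] = lHc
            lDc[:, :] = -1
            lVc[:, :] = -1
            lHc[:, :] = -1
            hstart[:] = -1
            hi_donor[:] = -1
            st_n[:] = 0
        for s in range(2):
            hi_n[s] = 0

        qres = np.int64(0)
        if r > 0:
            qres = np.int64(qs[r - 1])

        dptr0 = d0
        dptr1 = d0
        dptr2 = d0
        hptr = d0

        for c in range(0, w + 1):
            j = jlo + c

            if r >= 1:
                # ---------- D layer --------------------------------------
                bestD = NEG
                bw0 = np.int64(-1)
                bw1 = np.int64(-1)
                bw2 = np.int64(-1)
                if c >= 3 and caa[j] >= 0:
                    sub = np.int64(subm[qres, caa[j]])
                    cand = Dp[c - 3] + sub
                    if cand > bestD:
                        bestD = cand
                        bw0 = lDp[0, c - 3]
                        bw1 = lDp[1, c - 3]
                        bw2 = lDp[2, c - 3]
                    cand = Hp[c - 3] + sub
                    if cand > bestD:
                        bestD = cand
                        bw0 = lHp[0, c - 3]
                        bw1 = lHp[1, c - 3]
                        bw2 = lHp[2, c - 3]
                    cand = Vp[c - 3] + sub
                    if cand > bestD:
                        bestD = cand
                        bw0 = lVp[0, c - 3]
                        bw1 = lVp[1, c - 3]
                        bw2 = lVp[2, c - 3]
                for p in range(3):
                    ja = j - 3 + p
                    if ja - 2 < jlo or ja < jlo:
                        continue
                    if ja + (3 - p) > jhi:
                        continue
                    if p == 0:
                        dp = dptr0
                    elif p == 1:
                        dp = dptr1
                    else:
                        dp = dptr2
                    while dp < ndon and dpos[dp] <= ja - lmin:
                        jd = dpos[dp]
                        bcol = jd - p - jlo
                        if bcol >= 0 and jd + 2 <= jhi:
                            bval = Dp[bcol]
                            bl = np.int8(0)
                            w0b = lDp[0, bcol]
                            w1b = lDp[1, bcol]
                            w2b = lDp[2, bcol]
                            if Hp[bcol] > bval:
                                bval = Hp[bcol]
                                bl = np.int8(1)
                                w0b = lHp[0, bcol]
                                w1b = lHp[1, bcol]
                                w2b = lHp[2, bcol]
                            if bval > NEG_HALF:
                                code = np.int64(0)
                                if p == 1:
                                    code = np.int64(nt[jd - 1])
                                elif p == 2:
                                    code = np.int64(nt[jd - 2]) * 5 + np.int64(nt[jd - 1])
                                cls01 = 0 if dcls[dp] <= 1 else 1
                                val = bval + np.int64(dsc[dp])
                                sid = _stack_id(cls01, p, code)
                                nstk = st_n[sid]
                                while nstk > 0 and st_val[sid, nstk - 1] <= val:
                                    nstk -= 1
                                st_j[sid, nstk] = jd
                                st_val[sid, nstk] = val
                                st_bl[sid, nstk] = bl
                                st_w[0, sid, nstk] = w0b
                                st_w[1, sid, nstk] = w1b
                                st_w[2, sid, nstk] = w2b
                                st_n[sid] = nstk + 1
                        dp += 1
                    if p == 0:
                        dptr0 = dp
                    elif p == 1:
                        dptr1 = dp
                    else:
                        dptr2 = dp
                    acls = np.int64(acls_arr[ja])
                    if acls < 0:
                        continue
                    asc = np.int64(asc_arr[ja])
                    ncodes = 1 if p == 0 else (5 if p == 1 else 25)
                    for code in range(ncodes):
                        sid = _stack_id(acls, p, code)
                        nstk = st_n[sid]
                        if nstk == 0:
                            continue
                        aacol = _bridged_aa(code, p, nt, ja, codon2aa)
                        sub = np.int64(subm[qres, aacol])
                        beste = NEG
                        arge = -1
                        for e in range(nstk - 1, -1, -1):
                            candv = st_val[sid, e] - np.int64(pen[ja - st_j[sid, e]])
                            if candv > beste:
                                beste = candv
                                arge = e
                        total = beste + asc + sub
                        if total > bestD:
                            bestD = total
                            if prev_inter_c >= 0:
                                # departure from the intermediate row below:
                                # transmit arrival + packed jump record
                                bw0 = st_w[0, sid, arge]
                                bw1 = (np.int64(j) << 1) | 1
                                bw2 = (st_j[sid, arge] << 3) | (np.int64(p) << 1) \
                                    | np.int64(st_bl[sid, arge])
                                HL[prev_inter_c, 0, ja - jlo] = st_j[sid, arge]
                            else:
                                bw0 = st_w[0, sid, arge]
                                bw1 = st_w[1, sid, arge]
                                bw2 = st_w[2, sid, arge]
                if bestD > NEG_HALF:
                    Dc[c] = bestD
                    lDc[0, c] = bw0
                    lDc[1, c] = bw1
                    lDc[2, c] = bw2

                # ---------- V layer --------------------------------------
                bestV = NEG
                vw0 = np.int64(-1)
                vw1 = np.int64(-1)
                vw2 = np.int64(-1)
                cand = Dp[c] - v - u
                if cand > bestV:
                    bestV = cand
                    vw0 = lDp[0, c]
                    vw1 = lDp[1, c]
                    vw2 = lDp[2, c]
                cand = Vp[c] - u
                if cand > bestV:
                    bestV = cand
                    vw0 = lVp[0, c]
                    vw1 = lVp[1, c]
                    vw2 = lVp[2, c]
                if bestV > NEG_HALF:
                    Vc[c] = bestV
                    lVc[0, c] = vw0
                    lVc[1, c] = vw1
                    lVc[2, c] = vw2

            # ---------- H layer ------------------------------------------
            while hptr < ndon and dpos[hptr] <= (j - 3) - lmin:
                jd = dpos[hptr]
                bcol = jd - jlo
                if bcol >= 0 and jd + 2 <= jhi and Hc[bcol] > NEG_HALF:
                    cls01 = 0 if dcls[hptr] <= 1 else 1
                    val = Hc[bcol] + np.int64(dsc[hptr])
                    nstk = hi_n[cls01]
                    while nstk > 0 and hi_val[cls01, nstk - 1] <= val:
                        nstk -= 1
                    hi_jd[cls01, nstk] = jd
                    hi_val[cls01, nstk] = val
                    hi_hs[cls01, nstk] = hstart[bcol]
                    hi_w[0, cls01, nstk] = lHc[0, bcol]
                    hi_w[1, cls01, nstk] = lHc[1, bcol]
                    hi_w[2, cls01, nstk] = lHc[2, bcol]
                    hi_n[cls01] = nstk + 1
                hptr += 1
            bestH = NEG
            hw0 = np.int64(-1)
            hw1 = np.int64(-1)
            hw2 = np.int64(-1)
            hso = np.int64(-1)
            hdo = np.int64(-1)
            if c >= 3:
                cand = Dc[c - 3] - v - u
                if cand > bestH:
                    bestH = cand
                    hw0 = lDc[0, c - 3]
                    hw1 = lDc[1, c - 3]
                    hw2 = lDc[2, c - 3]
                    hso = np.int64(j - 3)  # gap origin: the D cell forked from
                cand = Hc[c - 3] - u
                if cand > bestH:
                    bestH = cand
                    hw0 = lHc[0, c - 3]
                    hw1 = lHc[1, c - 3]
                    hw2 = lHc[2, c - 3]
                    hso = hstart[c - 3]
                ja = j - 3
                if ja - 2 >= jlo:
                    acls = np.int64(acls_arr[ja])
                    if acls >= 0 and hi_n[acls] > 0:
                        asc = np.int64(asc_arr[ja])
                        beste = NEG
                        arge = -1
                        for e in range(hi_n[acls] - 1, -1, -1):
                            candv = hi_val[acls, e] - np.int64(pen[ja - hi_jd[acls, e]])
                            if candv > beste:
                                beste = candv
                                arge = e
                        total = beste + asc - u
                        if total > bestH:
                            bestH = total
                            hw0 = hi_w[0, acls, arge]
                            hw1 = hi_w[1, acls, arge]
                            hw2 = hi_w[2, acls, arge]
                            hso = hi_hs[acls, arge]
                            hdo = hi_jd[acls, arge]
            if bestH > NEG_HALF:
                Hc[c] = bestH
                lHc[0, c] = hw0
                lHc[1, c] = hw1
                lHc[2, c] = hw2
                hstart[c] = hso
                if hdo >= 0:
                    hi_donor[c] = hdo

        # ---------- snapshot + refresh at an intermediate row -------------
        prev_inter_c = -1
        if next_ic < k and r == inter[next_ic]:
            ci = next_ic
            for c in range(w + 1):
                VL_enc[ci, 0, c] = lDc[0, c]
                VL_enc[ci, 1, c] = lVc[0, c]
                if Dc[c] > NEG_HALF and lDc[1, c] >= 0:
                    wdict[(np.int64(ci) * 2 + 0) * (w + 1) + c] = \
                        (lDc[1, c] << 31) | lDc[2, c]
                if Vc[c] > NEG_HALF and lVc[1, c] >= 0:
                    wdict[(np.int64(ci) * 2 + 1) * (w + 1) + c] = \
                        (lVc[1, c] << 31) | lVc[2, c]
                if Hc[c] > NEG_HALF:
                    HL[ci, 0, c] = hstart[c]
                HL[ci, 1, c] = hi_donor[c]
                # refresh: cells on this row become their own crossing record
                if Dc[c] > NEG_HALF:
                    lDc[0, c] = (np.int64(jlo + c) << 1) | 0
                    lDc[1, c] = -1
                    lDc[2, c] = -1
                if Vc[c] > NEG_HALF:
                    lVc[0, c] = (np.int64(jlo + c) << 1) | 1
                    lVc[1, c] = -1
                    lVc[2, c] = -1
                if Hc[c] > NEG_HALF:
                    lHc[0, c] = (hstart[c] << 1) | 0
                    lHc[1, c] = -1
                    lHc[2, c] = -1
            prev_inter_c = ci
            next_ic += 1

    # ---- end ---------------------------------------------------------------
    if end_layer < 0:
        score = NEG
        end_c = 0
        end_l = LAYER_D
        for c in range(w + 1):
            if Dc[c] > score:
                score = Dc[c]
                end_c = c
                end_l = LAYER_D
            if Hc[c] > score:
                score = Hc[c]
                end_c = c
                end_l = LAYER_H
            if Vc[c] > score:
                score = Vc[c]
                end_c = c
                end_l = LAYER_V
    else:
        end_c = end_j - jlo
        end_l = end_layer
        if end_l == LAYER_D:
            score = Dc[end_c]
        elif end_l == LAYER_V:
            score = Vc[end_c]
        else:
            score = Hc[end_c]

    if end_l == LAYER_D:
        ew0, ew1, ew2 = lDc[0, end_c], lDc[1, end_c], lDc[2, end_c]
    elif end_l == LAYER_V:
        ew0, ew1, ew2 = lVc[0, end_c], lVc[1, end_c], lVc[2, end_c]
    else:
        ew0, ew1, ew2 = lHc[0, end_c], lHc[1, end_c], lHc[2, end_c]

    return score, end_c, end_l, ew0, ew1, ew2


@njit(cache=True)
def xdrop_extend(q_enc, taa, subm, i_seed, j_seed, xdrop):
    """Ungapped X-drop extension along one diagonal.

    Returns (q_start, q_end, score) of the maximum-scoring segment
    containing the seed start.
    """
    m = q_enc.shape[0]
    nj = taa.shape[0]
    best_right = np.int64(0)
    right_end = i_seed
    run = np.int64(0)
    i = i_seed
    while i < m:
        j = j_seed + 3 * (i - i_seed)
        if j < 0 or j >= nj:
            break
        run += subm[q_enc[i], taa[j]]
        if run > best_right:
            best_right = run
            right_end = i + 1
        if run < best_right - xdrop:
            break
        i += 1
    best_left = np.int64(0)
    left_start = i_seed
    run = np.int64(0)
    i = i_seed - 1
    while i >= 0:
        j = j_seed + 3 * (i - i_seed)
        if j < 0 or j >= nj:
            break
        run += subm[q_enc[i], taa[j]]
        if run > best_left:
            best_left = run
            left_start = i
        if run < best_left - xdrop:
            break
        i -= 1
    return left_start, right_end, best_left + best_right
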