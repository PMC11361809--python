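"""Shared fixtures and the independent scoring oracle.

The oracle scores the same move grammar as the production kernels but by
top-down memoised recursion with per-close donor loops — a different
algorithmic route from the bottom-up Pareto-pending kernels, usable as an
exhaustive reference at small problem sizes.
"""

from __future__ import annotations

import random
import sys
from functools import lru_cache

import pytest

from intronalign.scoring import (
    AA_INDEX,
    AA_ORDER,
    CODON2AA,
    IntronPenaltyModel,
    SpeciesParams,
    SpliceModel,
    codon_aa_indices,
    default_params,
    encode_nucleotides,
    encode_protein,
    find_splice_sites,
)
from intronalign.seqio import SequenceRecord

#: amino-acid index -> synonymous codons (for constructing exact fixtures)
SYNONYMS: dict[int, list[str]] = {}
for _i1, _a in enumerate("ACGT"):
    for _i2, _b in enumerate("ACGT"):
        for _i3, _c in enumerate("ACGT"):
            _aa = int(CODON2AA[16 * _i1 + 4 * _i2 + _i3])
            if _aa < 20:
                SYNONYMS.setdefault(_aa, []).append(_a + _b + _c)


def backtranslate(protein: str, rng: random.Random) -> str:
    return "".join(rng.choice(SYNONYMS[AA_INDEX[ch]]) for ch in protein)


def oracle_score(query: str, segment: str, params: SpeciesParams) -> int:
    """Exhaustive best spliced-alignment score by memoised recursion."""
    q = encode_protein(query)
    nt = encode_nucleotides(segment)
    caa = codon_aa_indices(nt)
    m, n = len(q), len(nt)
    subm = params.scheme.matrix
    v, u = params.scheme.gap_open, params.scheme.gap_extend
    lmin = params.intron.min_length
    donors, acceptors = find_splice_sites(segment, params.splice)
    acc_at = {pos: (cls, sc) for pos, cls, sc in acceptors}
    pen = params.intron.penalty_table(max(n, lmin), 1 << 28)
    NEG = -(1 << 29)
    sys.setrecursionlimit(200000)

    def sub_bridged(i, jd, ja, p):
        nts = list(nt[jd - p : jd]) + list(nt[ja : ja + 3 - p])
        col = 20 if any(x == 4 for x in nts) else \
            int(CODON2AA[16 * nts[0] + 4 * nts[1] + nts[2]])
        return int(subm[q[i - 1], col])

    @lru_cache(maxsize=None)
    def D(i, j):
        if i == 0:
            return 0
        best = NEG
        if j >= 3:
            s = int(subm[q[i - 1], caa[j]])
            best = max(D(i - 1, j - 3), V(i - 1, j - 3), H(i - 1, j - 3)) + s
        for p in (0, 1, 2):
            ja = j - 3 + p
            if ja < 2 or ja + (3 - p) > n or ja not in acc_at:
                continue
            acls, asc = acc_at[ja]
            for dpos, dcls, dsc in donors:
                if dpos > ja - lmin or dpos - p < 0 or dpos + 2 > n:
                    continue
                if (0 if dcls <= 1 else 1) != acls:
                    continue
                base = max(D(i - 1, dpos - p), H(i - 1, dpos - p))
                if base <= NEG // 2:
                    continue
                cand = base + dsc + asc - int(pen[ja - dpos]) + \
                    sub_bridged(i, dpos, ja, p)
                best = max(best, cand)
        return best

    @lru_cache(maxsize=None)
    def V(i, j):
        if i == 0:
            return NEG
        return max(D(i - 1, j) - v - u, V(i - 1, j) - u)

    @lru_cache(maxsize=None)
    def H(i, j):
        if j < 3:
            return NEG
        best = max(D(i, j - 3) - v - u, H(i, j - 3) - u)
        ja = j - 3
        if ja in acc_at:
            acls, asc = acc_at[ja]
            for dpos, dcls, dsc in donors:
                if dpos > ja - lmin or dpos + 2 > n:
                    continue
                if (0 if dcls <= 1 else 1) != acls:
                    continue
                base = H(i, dpos)
                if base <= NEG // 2:
                    continue
                best = max(best, base + dsc + asc - int(pen[ja - dpos]) - u)
        return best

    return max(max(D(m, j), V(m, j), H(m, j)) for j in range(n + 1))


def make_gene_instance(rng: random.Random, n_aa: int, n_introns: int,
                       flank: int = 50, intron_len=(35, 120)):
    """A clean multi-exon instance: (protein, segment, exon intervals)."""
    prot = "".join(rng.choice(AA_ORDER) for _ in range(n_aa))
    cds = backtranslate(prot, rng)
    points = sorted(rng.sample(range(3, len(cds) - 3), n_introns)) \
        if n_introns else []
    parts, exons = [], []
    left = "".join(rng.choice("ACGT") for _ in range(flank))
    pos = flank
    prev = 0
    for pt in points:
        parts.append(cds[prev:pt])
        exons.append((pos, pos + pt - prev))
        pos += pt - prev
        ilen = rng.randint(*intron_len)
        interior = list("".join(rng.choice("ACGT") for _ in range(ilen - 4)))
        if len(interior) >= 2 and interior[0] + interior[1] in ("GT", "GC", "AT"):
            interior[1] = "A"
        if interior and interior[-1] == "A":
            interior[-1] = "C"
        parts.append("GT" + "".join(interior) + "AG")
        pos += ilen
        prev = pt
    parts.append(cds[prev:])
    exons.append((pos, pos + len(cds) - prev))
    pos += len(cds) - prev
    right = "".join(rng.choice("ACGT") for _ in range(flank))
    seg = left + "".join(parts) + right
    return prot, seg, exons


@pytest.fixture(scope="session")
def params_full():
    return default_params("FULL")


@pytest.fixture(scope="session")
def params_const():
    return default_params("CONSTANT")


@pytest.fixture(scope="session")
def tiny_params():
    """Short minimum intron so tiny oracle instances can splice."""
    base = default_params("CONSTANT")
    return SpeciesParams(
        base.scheme, base.splice,
        IntronPenaltyModel(mode="CONSTANT", min_length=8, ip0=3),
    )


@pytest.fixture(scope="session")
def zero_signal_params():
    """CONSTANT ip0=5 with GT..AG only at zero signal score (worked examples)."""
    return SpeciesParams(
        default_params().scheme,
        SpliceModel(donor_scores={"GT": 0}, acceptor_scores={"AG": 0}),
        IntronPenaltyModel(mode="CONSTANT", ip0=5, min_length=30),
    )


def as_query(seq: str, name: str = "q") -> SequenceRecord:
    return SequenceRecord(name, seq)


def as_genome(seq: str, name: str = "g") -> SequenceRecord:
    return SequenceRecord(name, seq, alphabet="nucleotide")
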