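"""Seeded generator of synthetic eukaryotic genes and diverged queries.

Emulates the features the aligner has to cope with: multi-exon coding
genes with phase-0/1/2 introns, canonical GT..AG / GC..AG / AT..AC
boundaries at controlled frequencies, log-normal exon/intron lengths,
i.i.d. intergenic background at a configurable GC content, and query
proteins diverged to a target percent identity with substitution-matrix
biased replacements and short indels.

Codon usage is uniform over synonymous codons and intron interiors are
i.i.d.; neither codon bias nor branch-point structure is modelled.  The
first two interior bases after the donor and the third-from-last base
before the acceptor are constrained so that no equal-scoring slide of a
splice junction exists, which makes noise-free recovery of every exon
boundary a well-posed expectation rather than a coin flip on ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .scoring import AA_INDEX, AA_ORDER, CODON2AA
from .seqio import AnnotatedGene, SequenceRecord, write_fasta, write_gff3

#: amino-acid index -> list of synonymous codons
_SYNONYMS: dict[int, list[str]] = {}
for _i1, _a in enumerate("ACGT"):
    for _i2, _b in enumerate("ACGT"):
        for _i3, _c in enumerate("ACGT"):
            _aa = int(CODON2AA[16 * _i1 + 4 * _i2 + _i3])
            if _aa < 20:
                _SYNONYMS.setdefault(_aa, []).append(_a + _b + _c)

_DONOR_BY_CLASS = {0: "GT", 1: "GC", 2: "AT"}
_ACC_BY_CLASS = {0: "AG", 1: "AC"}
_DONOR_ACC_PAIR = {0: 0, 1: 0, 2: 1}  # AT donors pair with AC acceptors


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    gene_count: int = 50
    exon_count_range: tuple[int, int] = (1, 8)
    exon_length_median: float = 140.0     # nt
    exon_length_sigma: float = 0.5
    min_exon_length: int = 12             # nt
    intron_length_median: float = 300.0   # nt
    intron_length_sigma: float = 0.6
    min_intron_length: int = 30           # nt
    max_intron_length: int = 5000
    splice_class_freqs: tuple[float, float, float] = (0.98, 0.015, 0.005)
    intergenic_median: float = 2000.0     # nt
    intergenic_sigma: float = 0.5
    min_intergenic: int = 200
    gc_content: float = 0.45
    target_pid: float = 100.0
    indel_rate: float = 0.01              # indel events per residue
    force_phases: bool = True             # guarantee phase-1/2 introns per battery
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.splice_class_freqs) - 1.0) > 1e-9:
            raise ValueError("splice class frequencies must sum to 1")
        if self.min_intron_length < 1:
            raise ValueError("min intron length must be positive")


@dataclass
class TruthSet:
    """A genome, its annotation, native proteins and diverged queries."""

    genome: SequenceRecord
    genes: list[AnnotatedGene]
    proteins: list[SequenceRecord]
    queries: list[SequenceRecord]
    realized_pid: dict[str, float] = field(default_factory=dict)
    config: SimulationConfig | None = None

    def window(self, gene_id: str, margin: int = 200) -> tuple[int, int]:
        gene = next(g for g in self.genes if g.gene_id == gene_id)
        s, e = gene.span
        return max(0, s - margin), min(len(self.genome.residues), e + margin)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([self.genome], outdir / "genome.fa")
        write_gff3(self.genes, outdir / "truth.gff3")
        write_fasta(self.proteins, outdir / "proteins.fa")
        write_fasta(self.queries, outdir / "queries.fa")
        manifest = {
            "genes": [g.gene_id for g in self.genes],
            "realized_pid": self.realized_pid,
            "config": asdict(self.config) if self.config else None,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _random_nt(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _lognormal_len(rng, median: float, sigma: float, lo: int, hi: int | None = None) -> int:
    val = int(round(float(rng.lognormal(np.log(median), sigma))))
    val = max(val, lo)
    if hi is not None:
        val = min(val, hi)
    return val


def _sample_protein(rng: np.random.Generator, n_aa: int) -> str:
    return "".join(AA_ORDER[i] for i in rng.integers(0, 20, size=n_aa))


def _backtranslate(rng: np.random.Generator, protein: str) -> str:
    out = []
    for ch in protein:
        cods = _SYNONYMS[AA_INDEX[ch]]
        out.append(cods[rng.integers(0, len(cods))])
    return "".join(out)


def _make_intron(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[str, int]:
    """One intron sequence with class sampled at the configured frequencies.

    The first two interior bases avoid forming a second donor dinucleotide
    and the third-from-last base is non-A, which (with the canonical
    dinucleotides themselves) rules out any equal-length junction slide.
    """
    cls = int(rng.choice(3, p=np.array(cfg.splice_class_freqs)))
    length = _lognormal_len(rng, cfg.intron_length_median,
                            cfg.intron_length_sigma,
                            cfg.min_intron_length, cfg.max_intron_length)
    donor = _DONOR_BY_CLASS[cls]
    acceptor = _ACC_BY_CLASS[_DONOR_ACC_PAIR[cls]]
    interior = list(_random_nt(rng, length - 4, cfg.gc_content))
    # forbid a donor dinucleotide right after the real donor (no +2 slide)
    while len(interior) >= 2 and interior[0] + interior[1] in ("GT", "GC", "AT"):
        interior[1] = "ACGT"[rng.integers(0, 4)]
    # forbid an acceptor dinucleotide one base before the real one (no -1 slide)
    if len(interior) >= 1 and interior[-1] == "A":
        interior[-1] = "CGT"[rng.integers(0, 3)]
    return donor + "".join(interior) + acceptor, cls


def _split_points(rng: np.random.Generator, cfg: SimulationConfig,
                  coding_len: int, n_exons: int, force: bool) -> list[int]:
    """Cumulative coding positions of the introns, with optional phase forcing."""
    if n_exons <= 1:
        return []
    lo = cfg.min_exon_length
    while True:
        pts = sorted(rng.integers(lo, coding_len - lo, size=n_exons - 1).tolist())
        if all(b - a >= lo for a, b in zip(pts, pts[1:])):
            break
    if force and len(pts) >= 2:
        # nudge the first two splits onto phases 1 and 2
        pts[0] += (1 - pts[0]) % 3
        pts[1] += (2 - pts[1]) % 3
        pts = sorted(set(pts))
    return pts


def simulate_dataset(config: SimulationConfig) -> TruthSet:
    """Generate a genome with embedded genes, truth GFF3 structures, native
    proteins, and queries diverged to the configured target pid.

    Deterministic given the config seed; the spliced CDS of every gene
    translates exactly to its native protein.
    """
    rng = np.random.default_rng(config.seed)
    pieces: list[str] = []
    genes: list[AnnotatedGene] = []
    proteins: list[SequenceRecord] = []
    queries: list[SequenceRecord] = []
    pids: dict[str, float] = {}
    pos = 0
    for gi in range(config.gene_count):
        gap = _lognormal_len(rng, config.intergenic_median,
                             config.intergenic_sigma, config.min_intergenic)
        pieces.append(_random_nt(rng, gap, config.gc_content))
        pos += gap

        n_exons = int(rng.integers(config.exon_count_range[0],
                                   config.exon_count_range[1] + 1))
        total_aa = 0
        exon_targets = [
            _lognormal_len(rng, config.exon_length_median,
                           config.exon_length_sigma, config.min_exon_length)
            for _ in range(n_exons)
        ]
        coding_len = max(sum(exon_targets) // 3 * 3, 3 * n_exons * 4)
        total_aa = coding_len // 3
        protein = _sample_protein(rng, total_aa)
        cds = _backtranslate(rng, protein)
        splits = _split_points(rng, config, coding_len, n_exons,
                               config.force_phases)
        gene_id = f"gene{gi:04d}"
        exons_abs: list[tuple[int, int]] = []
        gene_seq_parts: list[str] = []
        prev = 0
        cur = pos
        for pt in splits:
            exon_nt = cds[prev:pt]
            gene_seq_parts.append(exon_nt)
            exons_abs.append((cur, cur + len(exon_nt)))
            cur += len(exon_nt)
            intron, _cls = _make_intron(rng, config)
            gene_seq_parts.append(intron)
            cur += len(intron)
            prev = pt
        exon_nt = cds[prev:]
        gene_seq_parts.append(exon_nt)
        exons_abs.append((cur, cur + len(exon_nt)))
        cur += len(exon_nt)

        gene_seq = "".join(gene_seq_parts)
        pieces.append(gene_seq)
        pos += len(gene_seq)

        genes.append(AnnotatedGene(gene_id, "synth_genome", "+", exons_abs))
        proteins.append(SequenceRecord(f"{gene_id}.prot", protein))
        qseed = int(rng.integers(0, 2**31 - 1))
        query = mutate_query(proteins[-1], config.target_pid,
                             config.indel_rate, qseed)
        query = SequenceRecord(f"{gene_id}.query", query.residues)
        queries.append(query)
        pids[query.id] = realized_pid(protein, query.residues)

    tail = _lognormal_len(rng, config.intergenic_median,
                          config.intergenic_sigma, config.min_intergenic)
    pieces.append(_random_nt(rng, tail, config.gc_content))
    genome = SequenceRecord("synth_genome", "".join(pieces),
                            alphabet="nucleotide")
    ts = TruthSet(genome, genes, proteins, queries, pids, config)
    for g, p in zip(genes, proteins):
        spliced = g.spliced_cds(genome.residues)
        if _translate(spliced) != p.residues:
            raise AssertionError(f"{g.gene_id}: CDS does not translate to protein")
    return ts


def _translate(cds: str) -> str:
    out = []
    for i in range(0, len(cds) - 2, 3):
        idx = 16 * "ACGT".index(cds[i]) + 4 * "ACGT".index(cds[i + 1]) + \
            "ACGT".index(cds[i + 2])
        aa = int(CODON2AA[idx])
        out.append(AA_ORDER[aa] if aa < 20 else "*")
    return "".join(out)


# substitution-biased replacement distribution per residue: P(b|a) ~ 2^(s(a,b)/2)
_BL = substitution_matrices.load("BLOSUM62")
_REPL: dict[str, tuple[list[str], np.ndarray]] = {}
for _a in AA_ORDER:
    others = [b for b in AA_ORDER if b != _a]
    wts = np.array([2.0 ** (_BL[_a][b] / 2.0) for b in others])
    _REPL[_a] = (others, wts / wts.sum())


def mutate_query(protein: SequenceRecord | str, target_pid: float,
                 indel_rate: float = 0.0, seed: int = 0) -> SequenceRecord:
    """Diverge a protein to an expected percent identity.

    Substitutions hit distinct positions (count = m*(1 - pid/100) rounded)
    with replacements drawn proportional to 2^(BLOSUM62/2); indel events
    (expected ``indel_rate`` per residue) insert or delete 1-3 residues.
    """
    if not (0 < target_pid <= 100):
        raise ValueError("target pid must be in (0, 100]")
    res = protein.residues if isinstance(protein, SequenceRecord) else str(protein)
    name = protein.id if isinstance(protein, SequenceRecord) else "query"
    rng = np.random.default_rng(seed)
    m = len(res)
    n_sub = int(round(m * (1.0 - target_pid / 100.0)))
    out = list(res)
    if n_sub > 0:
        for pos in rng.choice(m, size=n_sub, replace=False):
            a = res[pos]
            others, p = _REPL.get(a, (list(AA_ORDER), np.full(20, 0.05)))
            out[pos] = others[rng.choice(len(others), p=p)]
    n_indel = int(rng.poisson(indel_rate * m)) if indel_rate > 0 else 0
    for _ in range(n_indel):
        size = int(rng.integers(1, 4))
        if len(out) <= size + 2:
            break
        if rng.random() < 0.5:
            at = int(rng.integers(1, len(out) - size))
            del out[at : at + size]
        else:
            at = int(rng.integers(1, len(out)))
            ins = [AA_ORDER[i] for i in rng.integers(0, 20, size=size)]
            out[at:at] = ins
    return SequenceRecord(name, "".join(out))


_PID_ALIGNER: PairwiseAligner | None = None


def realized_pid(native: str, query: str) -> float:
    """Percent identity between two proteins after exact re-alignment.

    Global affine alignment under BLOSUM62; identity per the pid formula
    with internal gap columns counted half and terminal overhangs counted
    as unpaired residues (also half).
    """
    global _PID_ALIGNER
    if _PID_ALIGNER is None:
        a = PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -10
        a.extend_gap_score = -2
        try:
            a.end_insertion_score = 0
            a.end_deletion_score = 0
        except AttributeError:  # older Biopython naming
            a.target_end_gap_score = 0
            a.query_end_gap_score = 0
        _PID_ALIGNER = a
    aln = _PID_ALIGNER.align(native, query)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = mismatches = inner_gaps = 0
    first = None
    last = None
    for idx, (a_, b_) in enumerate(zip(s1, s2)):
        if a_ != "-" and b_ != "-":
            if first is None:
                first = idx
            last = idx
    unpaired = 0
    for idx, (a_, b_) in enumerate(zip(s1, s2)):
        if a_ == "-" or b_ == "-":
            if first is not None and first <= idx <= last:
                inner_gaps += 1
            else:
                unpaired += 1
        elif a_ == b_:
            matches += 1
        else:
            mismatches += 1
    denom = matches + mismatches + (inner_gaps + unpaired) / 2
    return 100.0 * matches / denom if denom else 0.0
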