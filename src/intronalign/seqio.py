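"""File formats, domain records and run configuration.

All internal coordinates are 0-based half-open; GFF3 output is 1-based
inclusive.  The conversion lives only in this module so that off-by-one
drift cannot creep in elsewhere.
"""

from __future__ import annotations

import configparser
import io
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .scoring import (
    AA_INDEX,
    NT_INDEX,
    IntronPenaltyModel,
    ScoringScheme,
    SpeciesParams,
    SpliceModel,
)

logger = logging.getLogger("intronalign")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.WARNING)


class ParseError(ValueError):
    """Malformed input file; the message names the offending record/line."""


# ---------------------------------------------------------------------------
# Sequence records
# ---------------------------------------------------------------------------

PROTEIN = "protein"
NUCLEOTIDE = "nucleotide"

_AA_ALPHA = set(AA_INDEX)
_NT_ALPHA = set(NT_INDEX) | {"N"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SequenceRecord:
    """One FASTA record with a declared, enforced alphabet."""

    id: str
    residues: str
    description: str = ""
    alphabet: str = PROTEIN

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence record with empty id")
        allowed = _AA_ALPHA if self.alphabet == PROTEIN else _NT_ALPHA
        wildcard = "X" if self.alphabet == PROTEIN else "N"
        res = self.residues.upper()
        if not set(res) <= allowed:
            res = "".join(c if c in allowed else wildcard for c in res)
        self.residues = res

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        if self.alphabet != NUCLEOTIDE:
            raise ValueError("reverse_complement only applies to nucleotide records")
        return SequenceRecord(
            self.id, self.residues.translate(_COMPLEMENT)[::-1],
            self.description, NUCLEOTIDE,
        )


def read_fasta(path, alphabet: str = PROTEIN) -> list[SequenceRecord]:
    """Read a multi-FASTA file, uppercasing and wildcard-mapping residues."""
    records: list[SequenceRecord] = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq)
            if not seq:
                raise ParseError(f"empty sequence for record {rec.id!r} in {path}")
            records.append(
                SequenceRecord(rec.id, seq, rec.description, alphabet)
            )
    if not records:
        raise ParseError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description and rec.description != rec.id else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotated genes and GFF3
# ---------------------------------------------------------------------------

@dataclass
class AnnotatedGene:
    """A gene as an ordered set of coding exons with codon phases.

    ``exons`` are 0-based half-open genomic intervals in ascending genomic
    order on both strands.  ``phases[e]`` is the codon phase at the start of
    exon ``e`` *in translation order* (cumulative preceding coding length
    mod 3): translation order is left-to-right on '+' and right-to-left on
    '-', so for minus-strand genes ``phases`` aligns with ``exons`` reversed.
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]
    phases: list[int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: empty exon list")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c < b:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        for a, b in self.exons:
            if b <= a:
                raise ValueError(f"gene {self.gene_id}: empty exon [{a},{b})")
        if self.phases is None:
            self.phases = self.computed_phases()

    def exons_in_translation_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def computed_phases(self) -> list[int]:
        phases, cum = [], 0
        for a, b in self.exons_in_translation_order():
            phases.append(cum % 3)
            cum += b - a
        return phases

    @property
    def coding_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def spliced_cds(self, genome: str) -> str:
        """Spliced coding sequence in translation order (reverse-complemented on '-')."""
        parts = [genome[a:b] for a, b in self.exons]
        cds = "".join(parts)
        if self.strand == "-":
            cds = cds.translate(_COMPLEMENT)[::-1]
        return cds


def write_gff3(genes: list[AnnotatedGene], path) -> None:
    """Write genes as gene/mRNA/CDS features (GFF3, 1-based inclusive).

    The CDS phase column holds the GFF3 frame, i.e. ``(3 - codon_phase) % 3``
    nucleotides to discard before the first complete codon.
    """
    lines = ["##gff-version 3"]
    for g in genes:
        if not g.exons:
            raise ValueError(f"gene {g.gene_id} has no exons")
        s, e = g.span
        attrs = f"ID={g.gene_id}"
        lines.append(
            f"{g.seq_id}\tintronalign\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}"
        )
        mrna_id = f"{g.gene_id}.mrna"
        lines.append(
            f"{g.seq_id}\tintronalign\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
            f"ID={mrna_id};Parent={g.gene_id}"
        )
        phases = g.phases if g.phases is not None else g.computed_phases()
        ordered = g.exons_in_translation_order()
        for (a, b), ph in zip(ordered, phases):
            gff_phase = (3 - ph) % 3
            lines.append(
                f"{g.seq_id}\tintronalign\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t"
                f"{gff_phase}\tID={g.gene_id}.cds;Parent={mrna_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path) -> list[AnnotatedGene]:
    """Read CDS features grouped by parent into :class:`AnnotatedGene` objects.

    Feature types other than gene/mRNA/CDS are ignored.  Phases are
    recomputed from cumulative exon lengths (from the rightmost exon for
    minus-strand genes), so round-trips through :func:`write_gff3` are exact.
    """
    mrna_parent: dict[str, str] = {}
    cds: dict[str, list[tuple[str, str, int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype == "mRNA":
                a = _parse_attrs(attrs)
                if "ID" in a and "Parent" in a:
                    mrna_parent[a["ID"]] = a["Parent"]
            elif ftype == "CDS":
                a = _parse_attrs(attrs)
                parent = a.get("Parent")
                if parent is None:
                    raise ParseError(f"{path}:{lineno}: CDS without Parent")
                gene = mrna_parent.get(parent, parent)
                if gene not in cds:
                    cds[gene] = []
                    order.append(gene)
                cds[gene].append((seqid, strand, int(start) - 1, int(end)))
    genes = []
    for gid in order:
        feats = cds[gid]
        seqid, strand = feats[0][0], feats[0][1]
        exons = sorted((a, b) for _s, _t, a, b in feats)
        for (a, b), (c, d) in zip(exons, exons[1:]):
            if c < b:
                raise ParseError(f"gene {gid}: overlapping CDS features")
        genes.append(AnnotatedGene(gid, seqid, strand, exons))
    return genes


# ---------------------------------------------------------------------------
# Species parameter files
# ---------------------------------------------------------------------------

_KNOWN = {
    "matrix": {"name", "stop_score"},
    "gaps": {"open", "extend"},
    "splice": {"gt", "gc", "at", "ag", "ac", "threshold"},
    "intron": {"mode", "min_length", "ip0", "alpha", "beta", "grain"},
}


def load_species_params(path) -> SpeciesParams:
    """Read a flat-text parameter file (sections [matrix] [gaps] [splice] [intron]).

    Absent keys fall back to the documented defaults; unknown keys trigger a
    warning; invalid values raise.  An empty file yields the full default
    parameter set.
    """
    cp = configparser.ConfigParser()
    text = Path(path).read_text()
    cp.read_string(text)
    for sect in cp.sections():
        if sect not in _KNOWN:
            logger.warning("parameter file %s: unknown section [%s]", path, sect)
            continue
        for key in cp[sect]:
            if key not in _KNOWN[sect]:
                logger.warning(
                    "parameter file %s: unknown key %s.%s", path, sect, key
                )

    def get(section, key, default, conv):
        try:
            raw = cp.get(section, key)
        except (configparser.NoSectionError, configparser.NoOptionError):
            return default
        try:
            return conv(raw)
        except Exception as exc:
            raise ParseError(f"{path}: invalid value for {section}.{key}: {raw!r}") from exc

    name = get("matrix", "name", "blosum62", str).lower()
    if name != "blosum62":
        raise ParseError(f"{path}: unsupported matrix {name!r}")
    scheme = ScoringScheme(
        gap_open=get("gaps", "open", 8, int),
        gap_extend=get("gaps", "extend", 2, int),
        stop_score=get("matrix", "stop_score", -50, int),
    )
    splice = SpliceModel(
        donor_scores={
            "GT": get("splice", "gt", 0, int),
            "GC": get("splice", "gc", -6, int),
            "AT": get("splice", "at", -8, int),
        },
        acceptor_scores={
            "AG": get("splice", "ag", 0, int),
            "AC": get("splice", "ac", -2, int),
        },
        threshold=get("splice", "threshold", -10, int),
    )
    intron = IntronPenaltyModel(
        mode=get("intron", "mode", "FULL", str),
        min_length=get("intron", "min_length", 30, int),
        ip0=get("intron", "ip0", 20, int),
        alpha=get("intron", "alpha", -15.0, float),
        beta=get("intron", "beta", 6.0, float),
        grain=get("intron", "grain", 1024, int),
    )
    return SpeciesParams(scheme=scheme, splice=splice, intron=intron)


def save_species_params(params: SpeciesParams, path) -> None:
    buf = io.StringIO()
    buf.write("[matrix]\nname = blosum62\n")
    buf.write(f"stop_score = {params.scheme.stop_score}\n\n")
    buf.write(f"[gaps]\nopen = {params.scheme.gap_open}\n")
    buf.write(f"extend = {params.scheme.gap_extend}\n\n")
    sp = params.splice
    buf.write("[splice]\n")
    buf.write(f"gt = {sp.donor_scores.get('GT', 0)}\n")
    buf.write(f"gc = {sp.donor_scores.get('GC', -6)}\n")
    buf.write(f"at = {sp.donor_scores.get('AT', -8)}\n")
    buf.write(f"ag = {sp.acceptor_scores.get('AG', 0)}\n")
    buf.write(f"ac = {sp.acceptor_scores.get('AC', -2)}\n")
    buf.write(f"threshold = {sp.threshold}\n\n")
    it = params.intron
    buf.write("[intron]\n")
    buf.write(f"mode = {it.mode}\nmin_length = {it.min_length}\nip0 = {it.ip0}\n")
    buf.write(f"alpha = {it.alpha}\nbeta = {it.beta}\ngrain = {it.grain}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Alignment-run switches shared by the CLI and the library API."""

    algorithm: str = "auto"          # auto | miudh | siudh | fullmatrix | banded
    penalty_mode: str = "FULL"       # FULL | COARSE | CONSTANT (or a0..a3 aliases)
    v_max: int = 16 * 1024 * 1024    # traceback memory budget, bytes
    band_width: int = 64             # codons of half-width for banded mode
    min_report_score: int = 35
    seed: int = 0
    output_format: str = "gff3"      # gff3 | table

    def __post_init__(self) -> None:
        if self.algorithm not in {"auto", "miudh", "siudh", "fullmatrix", "banded"}:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.v_max <= 0:
            raise ValueError("v_max must be positive")
        if self.algorithm == "banded" and self.band_width <= 0:
            raise ValueError("band width must be positive in banded mode")
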