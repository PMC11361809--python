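"""Gene-prediction accuracy metrics.

Three levels of accuracy over a set of query proteins, each paired
one-to-one with an annotated truth gene:

* mapping sensitivity MS — fraction of queries whose predicted genic span
  (first to last coding base) overlaps the annotated span by >= 1 base;
* gene level — a prediction is a true positive iff *all* predicted coding
  exon boundaries are identical to the annotated ones; GN = TP/(TP+FN)
  with TP+FN the number of queries, GP = TP/(TP+FP) with TP+FP the number
  of predicted genes;
* exon level — an exon is correct iff both its boundaries coincide with
  an annotated exon of the paired gene; EN = correct/annotated,
  EP = correct/predicted, EF their harmonic mean (F1).

Percent identity of an alignment is
``pid = 100 * matches / (matches + mismatches + (gaps + unpaired)/2)``
where "gaps" counts gap columns inside the aligned span and "unpaired"
counts query residues outside it (semi-global overhangs), making the two
terms disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import AnnotatedGene


@dataclass
class AlignmentStats:
    """Column counts of one alignment, the inputs of the pid formula."""

    matches: int = 0
    mismatches: int = 0
    gap_columns: int = 0
    unpaired: int = 0

    def __post_init__(self) -> None:
        for v in (self.matches, self.mismatches, self.gap_columns, self.unpaired):
            if v < 0:
                raise ValueError("alignment statistics must be non-negative")


@dataclass
class EvaluationReport:
    MS: float
    GN: float
    GP: float
    EN: float
    EP: float
    EF: float
    tp: int
    fn: int
    fp: int
    correct_exons: int
    annotated_exons: int
    predicted_exons: int


def percent_identity(stats: AlignmentStats) -> float:
    """pid = 100 * matches / (matches + mismatches + (gaps + unpaired)/2)."""
    denom = stats.matches + stats.mismatches + (stats.gap_columns + stats.unpaired) / 2
    if denom <= 0:
        raise ValueError("percent identity undefined for an all-zero alignment")
    return 100.0 * stats.matches / denom


def gene_exact_match(pred: AnnotatedGene, truth: AnnotatedGene):
    """Exact gene-level comparison plus per-exon boundary matches.

    Returns ``(exact, per_exon)`` where ``exact`` is True iff the two
    genes have identical exon interval lists, and ``per_exon[e]`` flags
    whether predicted exon e matches *some* annotated exon on both
    boundaries.
    """
    if pred.seq_id != truth.seq_id:
        return False, [False] * len(pred.exons)
    truth_set = set(truth.exons)
    per_exon = [ex in truth_set for ex in pred.exons]
    exact = (
        pred.strand == truth.strand
        and len(pred.exons) == len(truth.exons)
        and all(a == b for a, b in zip(pred.exons, truth.exons))
    )
    return exact, per_exon


def evaluate_sets(
    predictions: dict[str, AnnotatedGene | None],
    truths: dict[str, AnnotatedGene],
    pairing: dict[str, str] | None = None,
) -> EvaluationReport:
    """Score a prediction set against its truth set.

    ``predictions`` maps query id -> predicted gene (or None when the
    aligner reported nothing); ``truths`` maps truth gene id -> gene;
    ``pairing`` maps query id -> truth gene id (identity by default).
    Unpaired predictions count toward FP and the predicted-exon
    denominator only.
    """
    pairing = pairing or {qid: qid for qid in truths}
    n_queries = len(pairing)
    if n_queries == 0:
        raise ValueError("no query/truth pairs to evaluate")

    ms_hits = 0
    tp = 0
    n_pred = 0
    correct = annotated = predicted = 0
    for qid, tid in sorted(pairing.items()):
        truth = truths[tid]
        annotated += len(truth.exons)
        pred = predictions.get(qid)
        if pred is None:
            continue
        n_pred += 1
        predicted += len(pred.exons)
        ps, pe = pred.span
        ts, te = truth.span
        if pred.seq_id == truth.seq_id and ps < te and ts < pe:
            ms_hits += 1
        exact, per_exon = gene_exact_match(pred, truth)
        if exact:
            tp += 1
        correct += sum(per_exon)
    # predictions for queries outside the pairing: false positives
    for qid, pred in predictions.items():
        if qid not in pairing and pred is not None:
            n_pred += 1
            predicted += len(pred.exons)

    ms = ms_hits / n_queries
    gn = tp / n_queries
    gp = tp / n_pred if n_pred else 0.0
    en = correct / annotated if annotated else 0.0
    ep = correct / predicted if predicted else 0.0
    ef = 2 * en * ep / (en + ep) if (en + ep) > 0 else 0.0
    return EvaluationReport(
        MS=ms, GN=gn, GP=gp, EN=en, EP=ep, EF=ef,
        tp=tp, fn=n_queries - tp, fp=n_pred - tp,
        correct_exons=correct, annotated_exons=annotated,
        predicted_exons=predicted,
    )


def bin_by_pid(
    records: list[dict], width: float = 5.0
) -> list[dict]:
    """Pool per-query results into half-open pid bins [b, b+width).

    Each record needs a ``pid`` key; every other numeric key is averaged
    within the bin.  Empty bins are omitted; bins are returned in
    descending pid order (the direction in which accuracy decays).
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    bins: dict[float, list[dict]] = {}
    for rec in records:
        edge = (rec["pid"] // width) * width
        bins.setdefault(edge, []).append(rec)
    out = []
    for edge in sorted(bins, reverse=True):
        group = bins[edge]
        row = {"bin_low": edge, "bin_high": edge + width, "n": len(group)}
        keys = {k for g in group for k in g if k != "pid" and isinstance(g[k], (int, float))}
        for k in sorted(keys):
            vals = [g[k] for g in group if k in g]
            row[k] = sum(vals) / len(vals)
        row["pid"] = sum(g["pid"] for g in group) / len(group)
        out.append(row)
    return out
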