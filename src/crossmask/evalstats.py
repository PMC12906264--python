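"""Evaluation metrics for gene-prediction runs.

Covers the quantities used to compare analysis strategies: per-group gene
counts and length summaries; reference-based sensitivity and a
fragmentation index (mean number of distinct predicted calls overlapping
each detected true gene — > 1 means genes are being split); CDS
translation; and global-alignment percent identity between proteins.

Gene length everywhere means coding length (sum of exon lengths), not
genomic span, so intron-containing and single-CDS genes are comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Seq import Seq

from .maskengine import merge_intervals
from .seqmodel import ContigRecord, GeneCall, GeneSet, Interval
from .orffinder import revcomp

__all__ = [
    "SummaryStats",
    "EvaluationReport",
    "AlignScoring",
    "summarize",
    "compare_to_truth",
    "translate_cds",
    "percent_identity",
    "label_by_truth",
]

_CATEGORY_ORDER = ("eukaryote", "prokaryote", "virus", "unknown")
_PASS_ORDER = ("first_pass", "second_pass", "fallback", "truth")


@dataclass(frozen=True)
class SummaryStats:
    """Count/length summary for one group of calls."""

    group: str
    n_genes: int
    mean_len_nt: float
    median_len_nt: float
    total_len_nt: int


@dataclass(frozen=True)
class EvaluationReport:
    """Prediction set versus a truth annotation.

    A truth gene is *detected* when predictions cover at least
    ``overlap_frac`` of its coding length; ``fragmentation`` averages, over
    detected truth genes, the number of distinct predicted calls with any
    coding-base overlap; ``mean_len_ratio`` is mean predicted coding
    length over mean truth coding length.
    """

    n_truth: int
    n_pred: int
    detected: int
    sensitivity: float
    fragmentation: float
    mean_len_ratio: float


@dataclass(frozen=True)
class AlignScoring:
    """Linear-gap global alignment scoring."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0

    def __post_init__(self) -> None:
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if self.gap >= 0:
            raise ValueError("gap penalty must be negative")


def _median_lower(sorted_vals: list[int]) -> float:
    # lower-middle element for even counts, for determinism
    return float(sorted_vals[(len(sorted_vals) - 1) // 2])


def summarize(gene_set: GeneSet, group_by: str = "none") -> list[SummaryStats]:
    """Per-group gene counts and coding-length summaries.

    ``group_by`` is "category", "source_pass" or "none" (one row labeled
    "all"). Group order is fixed; only non-empty groups are reported,
    except that an empty input yields a single zero row.
    """
    if group_by == "none":
        groups = {"all": list(gene_set.calls)}
        order = ["all"]
    elif group_by == "category":
        groups = {}
        for call in gene_set.calls:
            groups.setdefault(call.category, []).append(call)
        order = [g for g in _CATEGORY_ORDER if g in groups]
    elif group_by == "source_pass":
        groups = {}
        for call in gene_set.calls:
            groups.setdefault(call.source_pass, []).append(call)
        order = [g for g in _PASS_ORDER if g in groups]
    else:
        raise ValueError(f"bad group_by {group_by!r}")
    if not gene_set.calls:
        label = "all" if group_by == "none" else "(empty)"
        return [SummaryStats(label, 0, math.nan, math.nan, 0)]
    out = []
    for label in order:
        lengths = sorted(c.coding_length for c in groups[label])
        total = sum(lengths)
        out.append(
            SummaryStats(
                group=label,
                n_genes=len(lengths),
                mean_len_nt=total / len(lengths),
                median_len_nt=_median_lower(lengths),
                total_len_nt=total,
            )
        )
    return out


def _coding_overlap(a_exons: list[Interval], b_merged: list[Interval]) -> int:
    """Overlapping bases between exon list a and a merged interval list."""
    total = 0
    for ex in a_exons:
        for iv in b_merged:
            if iv.start >= ex.end:
                break
            lo, hi = max(ex.start, iv.start), min(ex.end, iv.end)
            if lo < hi:
                total += hi - lo
    return total


def compare_to_truth(
    pred: GeneSet,
    truth: GeneSet,
    overlap_frac: float = 0.5,
    strand_aware: bool = True,
) -> EvaluationReport:
    """Score a prediction set against a truth annotation.

    Coverage of each truth gene is computed from the union of predicted
    exon intervals on the same contig (and strand, unless
    ``strand_aware=False``).
    """
    if not (0 < overlap_frac <= 1):
        raise ValueError(f"overlap_frac must be in (0, 1], got {overlap_frac}")

    def key(contig: str, strand: str) -> tuple:
        return (contig, strand) if strand_aware else (contig,)

    pred_exons: dict[tuple, list[Interval]] = {}
    pred_calls: dict[tuple, list[GeneCall]] = {}
    for call in pred.calls:
        k = key(call.contig_id, call.strand)
        pred_exons.setdefault(k, []).extend(call.exons)
        pred_calls.setdefault(k, []).append(call)
    merged = {k: merge_intervals(v) for k, v in pred_exons.items()}

    detected = 0
    frag_counts: list[int] = []
    for t in truth.calls:
        k = key(t.contig_id, t.strand)
        cov = _coding_overlap(t.exons, merged.get(k, []))
        if cov >= overlap_frac * t.coding_length:
            detected += 1
            n_frag = sum(
                1
                for p in pred_calls.get(k, [])
                if _coding_overlap(t.exons, merge_intervals(p.exons)) > 0
            )
            frag_counts.append(n_frag)

    n_truth, n_pred = len(truth.calls), len(pred.calls)
    mean_pred = (
        sum(c.coding_length for c in pred.calls) / n_pred if n_pred else math.nan
    )
    mean_truth = (
        sum(c.coding_length for c in truth.calls) / n_truth if n_truth else math.nan
    )
    return EvaluationReport(
        n_truth=n_truth,
        n_pred=n_pred,
        detected=detected,
        sensitivity=detected / n_truth if n_truth else 0.0,
        fragmentation=sum(frag_counts) / len(frag_counts) if frag_counts else 0.0,
        mean_len_ratio=mean_pred / mean_truth if n_truth and n_pred else math.nan,
    )


def extract_cds(call: GeneCall, contig: ContigRecord) -> str:
    """Concatenate a call's exons in coding orientation (upper-cased)."""
    if call.contig_id != contig.id:
        raise ValueError(f"call {call.gene_id!r} is on contig {call.contig_id!r}, not {contig.id!r}")
    if call.span.end > len(contig.seq):
        raise ValueError(f"call {call.gene_id!r} exceeds contig {contig.id!r}")
    cds = "".join(contig.seq[ex.start : ex.end] for ex in call.exons).upper()
    return revcomp(cds) if call.strand == "-" else cds


def translate_cds(
    call: GeneCall,
    contig: ContigRecord,
    table: int = 11,
    partial_ok: bool = False,
) -> str:
    """Translate a call's CDS to protein under the given genetic code.

    Minus-strand calls are reverse-complemented after exon concatenation.
    An initiator codon of the table's start set is rendered as 'M'
    (predictor convention); the terminal stop is stripped. An internal
    stop raises unless ``partial_ok``.
    """
    cds = extract_cds(call, contig)
    if len(cds) % 3 != 0:
        raise ValueError(
            f"call {call.gene_id!r}: coding length {len(cds)} is not a multiple of 3"
        )
    protein = str(Seq(cds).translate(table=table))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein and not partial_ok:
        raise ValueError(f"call {call.gene_id!r}: internal stop codon in translation")
    if protein and cds[:3] in ("ATG", "GTG", "TTG"):
        protein = "M" + protein[1:]
    return protein


def percent_identity(
    a: str, b: str, scoring: AlignScoring = AlignScoring()
) -> float:
    """Percent identity of the optimal global (end-to-end) alignment.

    Identity = 100 x matches / alignment columns (gap columns included).
    Among equally scoring alignments the one with the fewest gap columns
    is used; score and gap count together fix the match count, so the
    result is deterministic. Symmetric, and 100.0 for identical inputs.
    """
    if not a or not b:
        raise ValueError("percent_identity requires non-empty sequences")
    la, lb = len(a), len(b)
    gap, match, mismatch = scoring.gap, scoring.match, scoring.mismatch
    # DP over (score, -gap_columns), lexicographic max; both keys additive.
    prev = [(j * gap, -j) for j in range(lb + 1)]
    for i in range(1, la + 1):
        cur = [(i * gap, -i)]
        ai = a[i - 1]
        for j in range(1, lb + 1):
            s = match if ai == b[j - 1] else mismatch
            pd = prev[j - 1]
            pu = prev[j]
            pl = cur[j - 1]
            best = (pd[0] + s, pd[1])
            up = (pu[0] + gap, pu[1] - 1)
            if up > best:
                best = up
            left = (pl[0] + gap, pl[1] - 1)
            if left > best:
                best = left
            cur.append(best)
        prev = cur
    score, neg_gaps = prev[lb]
    g = -neg_gaps
    pairs = (la + lb - g) // 2
    columns = pairs + g
    matches = (score - gap * g - mismatch * pairs) / (match - mismatch)
    return 100.0 * matches / columns


def label_by_truth(pred: GeneSet, truth: GeneSet) -> GeneSet:
    """Transfer truth categories onto predictions by coding overlap.

    Each prediction takes the category of the same-contig, same-strand
    truth gene with the largest coding overlap (ties to the first in truth
    order); predictions overlapping nothing keep category "unknown". The
    simulator's ground truth plays the role an external taxonomic
    annotator would on real data.
    """
    from dataclasses import replace

    truth_by_key: dict[tuple[str, str], list[GeneCall]] = {}
    for t in truth.calls:
        truth_by_key.setdefault((t.contig_id, t.strand), []).append(t)
    calls = []
    for p in pred.calls:
        best_cat, best_ov = "unknown", 0
        for t in truth_by_key.get((p.contig_id, p.strand), []):
            ov = _coding_overlap(t.exons, merge_intervals(p.exons))
            if ov > best_ov:
                best_cat, best_ov = t.category, ov
        calls.append(replace(p, category=best_cat) if best_ov else p)
    return GeneSet(pred.name, calls, dict(pred.provenance))
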