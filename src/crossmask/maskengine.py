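"""Alignment-free hard-masking of predicted gene regions.

This is the stage that makes the staged workflow scale: instead of
re-aligning anything, the genomic intervals of all first-pass calls are
collected per contig, merged into a disjoint union, and the covered bases
are overwritten with 'N'. A downstream ab initio predictor then cannot
re-call genes in those regions, so its output is non-redundant with the
first pass by construction.

Masking is strand-agnostic ('N' destroys both strands) and operates on one
contig's sequence at a time, so memory stays proportional to the largest
contig, not the metagenome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqmodel import ContigRecord, GeneSet, Interval, IUPAC_DNA

__all__ = [
    "MaskPolicy",
    "MaskReport",
    "intervals_from_calls",
    "merge_intervals",
    "apply_mask",
    "mask_metagenome",
]


@dataclass(frozen=True)
class MaskPolicy:
    """How gene calls map to masked intervals.

    mode="span" masks each call's whole genomic span (introns included);
    mode="exons" masks only coding exons. Span is the default: unmasked
    introns would invite spurious second-pass calls inside eukaryotic
    genes. Intervals separated by at most ``merge_gap`` bases are fused
    before masking; 0 still fuses touching intervals.
    """

    mode: str = "span"
    mask_char: str = "N"
    merge_gap: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("span", "exons"):
            raise ValueError(f"bad mask mode {self.mode!r}")
        if len(self.mask_char) != 1 or self.mask_char.upper() not in IUPAC_DNA:
            raise ValueError(f"mask_char must be one IUPAC character, got {self.mask_char!r}")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be non-negative")


@dataclass
class MaskReport:
    """Masked-base accounting for one masking run."""

    per_contig: dict[str, tuple[int, int]] = field(default_factory=dict)
    total_masked: int = 0
    total_bases: int = 0
    skipped_calls: int = 0  # calls on absent contigs, when running lenient

    @property
    def fraction_masked(self) -> float:
        return self.total_masked / self.total_bases if self.total_bases else 0.0

    def to_tsv(self, contig_lengths: dict[str, int]) -> str:
        lines = ["contig\tlength\tmasked_bases\tn_intervals\tfraction"]
        for contig_id, (masked, n_iv) in self.per_contig.items():
            length = contig_lengths[contig_id]
            lines.append(
                f"{contig_id}\t{length}\t{masked}\t{n_iv}\t{masked / length:.6f}"
            )
        lines.append(
            f"TOTAL\t{self.total_bases}\t{self.total_masked}\t-\t{self.fraction_masked:.6f}"
        )
        return "\n".join(lines) + "\n"


def intervals_from_calls(
    gene_set: GeneSet, policy: MaskPolicy = MaskPolicy()
) -> dict[str, list[Interval]]:
    """Collect the to-be-masked intervals of every call, grouped by contig."""
    out: dict[str, list[Interval]] = {}
    for call in gene_set.calls:
        ivs = out.setdefault(call.contig_id, [])
        if policy.mode == "span":
            ivs.append(call.span)
        else:
            ivs.extend(call.exons)
    return out


def merge_intervals(intervals: list[Interval], merge_gap: int = 0) -> list[Interval]:
    """Merge intervals into a sorted disjoint union.

    Intervals whose gap is <= ``merge_gap`` are fused (gap 0 = touching).
    Idempotent; handles nested, duplicate and unsorted input.
    """
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [ordered[0]]
    for iv in ordered[1:]:
        last = merged[-1]
        if iv.start - last.end <= merge_gap:
            if iv.end > last.end:
                merged[-1] = Interval(last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def apply_mask(
    contig: ContigRecord,
    intervals: list[Interval],
    mask_char: str = "N",
) -> tuple[ContigRecord, int]:
    """Overwrite ``intervals`` of one contig with ``mask_char``.

    ``intervals`` must already be sorted and disjoint (see
    :func:`merge_intervals`). Positions outside the intervals are
    byte-identical to the input; the sequence length never changes.
    Returns the masked record and the number of masked bases.
    """
    if not intervals:
        return contig, 0
    length = len(contig.seq)
    prev_end = -1
    for iv in intervals:
        if iv.start < prev_end:
            raise ValueError(f"contig {contig.id!r}: intervals not sorted/disjoint at {iv}")
        if iv.end > length:
            raise ValueError(
                f"contig {contig.id!r}: interval [{iv.start}, {iv.end}) "
                f"exceeds contig length {length}"
            )
        prev_end = iv.end
    buf = bytearray(contig.seq, "ascii")
    mask_byte = ord(mask_char)
    masked = 0
    for iv in intervals:
        buf[iv.start : iv.end] = bytes([mask_byte]) * len(iv)
        masked += len(iv)
    return ContigRecord(contig.id, buf.decode("ascii"), contig.description), masked


def mask_metagenome(
    contigs: list[ContigRecord],
    gene_set: GeneSet,
    policy: MaskPolicy = MaskPolicy(),
    lenient: bool = False,
) -> tuple[list[ContigRecord], MaskReport]:
    """Hard-mask every predicted gene region across a contig collection.

    Composes interval collection, union merging and per-contig
    substitution. Contigs without calls pass through unchanged (same
    object). Calls that reference an absent contig raise, unless
    ``lenient`` downgrades them to a counted warning in the report.
    """
    by_contig = intervals_from_calls(gene_set, policy)
    known = {c.id for c in contigs}
    report = MaskReport()
    missing = set(by_contig) - known
    if missing and not lenient:
        raise ValueError(
            f"gene calls reference absent contig(s): {sorted(missing)}"
        )
    if missing:
        report.skipped_calls = sum(
            1 for c in gene_set.calls if c.contig_id in missing
        )
    masked_contigs: list[ContigRecord] = []
    for contig in contigs:
        report.total_bases += len(contig.seq)
        ivs = by_contig.get(contig.id)
        if not ivs:
            masked_contigs.append(contig)
            continue
        merged = merge_intervals(ivs, policy.merge_gap)
        masked_rec, n_masked = apply_mask(contig, merged, policy.mask_char)
        masked_contigs.append(masked_rec)
        report.per_contig[contig.id] = (n_masked, len(merged))
        report.total_masked += n_masked
    return masked_contigs, report
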