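"""Core domain types and FASTA/GFF3 readers and writers.

All coordinates are 0-based half-open internally ([start, end)); GFF3 I/O
converts to and from the 1-based inclusive convention of that format.
Exon lists are kept in ascending forward-strand order regardless of strand:
strand is consulted only when a coding sequence is extracted for
translation, never for masking or interval arithmetic.

Sequence case is preserved on input and output so that upstream
soft-masking survives a round trip; character validation and codon
comparisons are case-insensitive.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Union

from Bio import SeqIO

__all__ = [
    "IUPAC_DNA",
    "ContigRecord",
    "Interval",
    "GeneCall",
    "GeneSet",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
]

#: Unambiguous bases, N, and the IUPAC ambiguity codes.
IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")

SOURCE_PASSES = ("first_pass", "second_pass", "fallback", "truth")
CATEGORIES = ("eukaryote", "prokaryote", "virus", "unknown")
STRANDS = ("+", "-")

TextSource = Union[str, os.PathLike, IO[str]]


def _open_text(source: TextSource) -> tuple[IO[str], bool]:
    """Return (handle, needs_close) for a path or an already-open handle."""
    if isinstance(source, (str, os.PathLike)):
        return open(source, "rt"), True
    return source, False


@dataclass
class ContigRecord:
    """One assembled contig: identifier plus DNA sequence.

    ``id`` must be a non-empty whitespace-free token; ``seq`` may use any
    IUPAC DNA code in either case.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"contig id must be a non-empty token, got {self.id!r}")
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval [start, end), 0-based."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class GeneCall:
    """A predicted (or true) gene on one contig.

    ``span`` and ``exons`` are forward-strand half-open intervals; exons are
    sorted ascending and pairwise disjoint even for minus-strand calls. A
    single-CDS gene has exactly one exon equal to its span. ``source_pass``
    records which stage produced the call, ``category`` the domain label
    when known.
    """

    gene_id: str
    contig_id: str
    span: Interval
    strand: str
    exons: list[Interval]
    source_pass: str = "first_pass"
    category: str = "unknown"
    score: float | None = None
    evalue: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if self.source_pass not in SOURCE_PASSES:
            raise ValueError(f"gene {self.gene_id!r}: bad source_pass {self.source_pass!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"gene {self.gene_id!r}: bad category {self.category!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id!r}: empty exon list")
        if self.evalue is not None and self.evalue < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative e-value")
        prev_end = None
        for ex in self.exons:
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError(f"gene {self.gene_id!r}: exon {ex} outside span {self.span}")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.gene_id!r}: exons overlap or are unsorted")
            prev_end = ex.end

    @property
    def coding_length(self) -> int:
        """Sum of exon lengths (the gene length used for all statistics)."""
        return sum(len(ex) for ex in self.exons)


@dataclass
class GeneSet:
    """A named collection of gene calls with unique identifiers."""

    name: str
    calls: list[GeneCall] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for call in self.calls:
            if call.gene_id in seen:
                raise ValueError(f"duplicate gene_id {call.gene_id!r} in set {self.name!r}")
            seen.add(call.gene_id)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[GeneCall]:
        return iter(self.calls)

    def ids(self) -> set[str]:
        return {c.gene_id for c in self.calls}

    def with_source_pass(self, source_pass: str) -> "GeneSet":
        calls = [replace(c, source_pass=source_pass) for c in self.calls]
        return GeneSet(self.name, calls, dict(self.provenance))


# ---------------------------------------------------------------------------
# FASTA


def _validate_seq(contig_id: str, seq: str) -> None:
    for pos, ch in enumerate(seq):
        if ch.upper() not in IUPAC_DNA:
            raise ValueError(
                f"contig {contig_id!r}: illegal character {ch!r} at position {pos}"
            )


def read_fasta(source: TextSource) -> list[ContigRecord]:
    """Read a (possibly line-wrapped) multi-FASTA into ContigRecords.

    Order and case are preserved. Duplicate ids and non-IUPAC characters
    raise ``ValueError``.
    """
    handle, needs_close = _open_text(source)
    try:
        records: list[ContigRecord] = []
        seen: set[str] = set()
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq)
            _validate_seq(rec.id, seq)
            desc = rec.description[len(rec.id):].strip() if rec.description else ""
            records.append(ContigRecord(rec.id, seq, desc))
        return records
    finally:
        if needs_close:
            handle.close()


def read_fasta_str(text: str) -> list[ContigRecord]:
    """Parse FASTA from an in-memory string."""
    return read_fasta(io.StringIO(text))


def write_fasta(records: Iterable[ContigRecord], wrap: int = 60) -> str:
    """Render records as multi-FASTA text with lines wrapped at ``wrap``."""
    if wrap < 1:
        raise ValueError(f"wrap must be >= 1, got {wrap}")
    out: list[str] = []
    for rec in records:
        header = f">{rec.id}"
        if rec.description:
            header += f" {rec.description}"
        out.append(header)
        for i in range(0, len(rec.seq), wrap):
            out.append(rec.seq[i : i + wrap])
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# GFF3

_GFF_HEADER = "##gff-version 3"


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
    return attrs


def read_gff(source: TextSource) -> GeneSet:
    """Read GFF3 CDS features into a GeneSet.

    CDS rows sharing a Parent (or, failing that, an ID) become the exons of
    one call; GFF 1-based inclusive coordinates are converted to half-open.
    Optional ``category``/``source_pass`` attributes written by this
    package's emitter are restored when present.
    """
    handle, needs_close = _open_text(source)
    try:
        groups: dict[str, dict] = {}
        order: list[str] = []
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"GFF line {lineno}: expected 9 columns, got {len(cols)}")
            seqid, _src, ftype, start_s, end_s, score_s, strand, _phase, attr_s = cols
            if ftype.upper() != "CDS":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"GFF line {lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise ValueError(f"GFF line {lineno}: end {end1} < start {start1}")
            if strand not in STRANDS:
                raise ValueError(f"GFF line {lineno}: unknown strand {strand!r}")
            attrs = _parse_attributes(attr_s)
            key = attrs.get("Parent") or attrs.get("ID")
            if not key:
                raise ValueError(f"GFF line {lineno}: CDS without ID or Parent")
            grp = groups.get(key)
            if grp is None:
                grp = {
                    "contig": seqid,
                    "strand": strand,
                    "exons": [],
                    "score": None if score_s == "." else float(score_s),
                    "evalue": float(attrs["evalue"]) if "evalue" in attrs else None,
                    "category": attrs.get("category", "unknown"),
                    "source_pass": attrs.get("source_pass", "first_pass"),
                    "n_cds": 0,
                }
                groups[key] = grp
                order.append(key)
            elif grp["contig"] != seqid or grp["strand"] != strand:
                raise ValueError(f"GFF group {key!r}: inconsistent contig or strand")
            grp["exons"].append(Interval(start1 - 1, end1))
            grp["n_cds"] += 1
        calls = []
        for key in order:
            grp = groups[key]
            exons = sorted(grp["exons"])
            span = Interval(exons[0].start, exons[-1].end)
            calls.append(
                GeneCall(
                    gene_id=key,
                    contig_id=grp["contig"],
                    span=span,
                    strand=grp["strand"],
                    exons=exons,
                    source_pass=grp["source_pass"],
                    category=grp["category"],
                    score=grp["score"],
                    evalue=grp["evalue"],
                )
            )
        return GeneSet("gff", calls)
    finally:
        if needs_close:
            handle.close()


def read_gff_str(text: str) -> GeneSet:
    """Parse GFF3 from an in-memory string."""
    return read_gff(io.StringIO(text))


def _cds_phases(call: GeneCall) -> list[int]:
    """GFF3 phase per exon, computed in translation order (strand-aware)."""
    exons = call.exons if call.strand == "+" else list(reversed(call.exons))
    phases, cum = [], 0
    for ex in exons:
        phases.append((3 - cum % 3) % 3)
        cum += len(ex)
    return phases if call.strand == "+" else list(reversed(phases))


def write_gff(gene_set: GeneSet) -> str:
    """Render a GeneSet as GFF3 with gene + CDS features.

    All CDS rows of a call carry ``Parent=<gene_id>`` so multi-exon calls
    regroup on read; ``read_gff(write_gff(s))`` reproduces contig, span,
    strand, exons and gene_id exactly.
    """
    lines = [_GFF_HEADER]
    for call in gene_set.calls:
        score = "." if call.score is None else format(call.score, "g")
        gene_attrs = f"ID={call.gene_id}"
        lines.append(
            "\t".join(
                [
                    call.contig_id,
                    "crossmask",
                    "gene",
                    str(call.span.start + 1),
                    str(call.span.end),
                    ".",
                    call.strand,
                    ".",
                    gene_attrs,
                ]
            )
        )
        extra = f";category={call.category};source_pass={call.source_pass}"
        if call.evalue is not None:
            extra += f";evalue={call.evalue:g}"
        for ex, phase in zip(call.exons, _cds_phases(call)):
            lines.append(
                "\t".join(
                    [
                        call.contig_id,
                        "crossmask",
                        "CDS",
                        str(ex.start + 1),
                        str(ex.end),
                        score,
                        call.strand,
                        str(phase),
                        f"Parent={call.gene_id}" + extra,
                    ]
                )
            )
    return "\n".join(lines) + "\n"
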