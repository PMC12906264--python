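"""Parsers for first-pass and second-pass gene-predictor outputs.

The first-pass (homology-based, MetaEuk-style) predictor encodes exact gene
locations either in GFF3 or directly in the headers of its predictions
FASTA; both routes are supported and yield identical GeneSets for the same
underlying predictions. The second-pass (ab initio, Prodigal/MetaGeneMark
style) predictors emit single-CDS GFF3.

Header layouts differ between predictor versions, so the pipe-delimited
dialect is configurable via :class:`HeaderDialect`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

from .seqmodel import (
    GeneCall,
    GeneSet,
    Interval,
    TextSource,
    _open_text,
    read_gff,
)

__all__ = [
    "HeaderDialect",
    "DEFAULT_DIALECT",
    "parse_metaeuk_headers",
    "parse_metaeuk_gff",
    "parse_prokaryotic_gff",
    "clip_to_contigs",
]

_ROLES = (
    "target",
    "contig",
    "strand",
    "bitscore",
    "evalue",
    "exon_count",
    "low_coord",
    "high_coord",
    "exon_blocks",
)


@dataclass(frozen=True)
class HeaderDialect:
    """Layout of one pipe-delimited prediction header.

    ``field_order`` maps each of the nine roles to its position. The
    default layout is::

        target|contig|strand|bitscore|evalue|n_exons|low|high|blocks

    where ``blocks`` is a colon-separated list of ``low-high`` exon
    coordinate pairs in ``coordinate_base`` convention ("0-inclusive":
    both coordinates 0-based inclusive, half-open end = high + 1;
    "1-inclusive": 1-based inclusive as in GFF).
    """

    field_separator: str = "|"
    coordinate_base: str = "0-inclusive"
    field_order: dict[str, int] = field(
        default_factory=lambda: {role: i for i, role in enumerate(_ROLES)}
    )

    def __post_init__(self) -> None:
        if self.coordinate_base not in ("0-inclusive", "1-inclusive"):
            raise ValueError(f"bad coordinate_base {self.coordinate_base!r}")
        if set(self.field_order) != set(_ROLES):
            missing = set(_ROLES) - set(self.field_order)
            raise ValueError(f"field_order must map all nine roles (missing {missing})")
        if len(set(self.field_order.values())) != len(_ROLES):
            raise ValueError("field_order positions must be distinct")

    @property
    def n_fields(self) -> int:
        return max(self.field_order.values()) + 1

    def to_halfopen(self, low: int, high: int) -> Interval:
        if self.coordinate_base == "0-inclusive":
            return Interval(low, high + 1)
        return Interval(low - 1, high)

    def from_halfopen(self, iv: Interval) -> tuple[int, int]:
        if self.coordinate_base == "0-inclusive":
            return iv.start, iv.end - 1
        return iv.start + 1, iv.end


DEFAULT_DIALECT = HeaderDialect()

_STRAND_ALIASES = {"+": "+", "-": "-", "+1": "+", "-1": "-", "1": "+"}


def _parse_coord(token: str, header: str) -> int:
    try:
        return int(token)
    except ValueError as exc:
        raise ValueError(f"non-numeric coordinate {token!r} in header {header!r}") from exc


def parse_metaeuk_headers(
    source: TextSource, dialect: HeaderDialect = DEFAULT_DIALECT
) -> GeneSet:
    """Parse first-pass predictions from FASTA headers; bodies are ignored.

    Each header encodes one gene call in the dialect's layout. Calls are
    tagged ``source_pass="first_pass"``. Repeated target names are made
    unique with a numeric suffix (the target is an aligned reference, not a
    gene identifier).
    """
    handle, needs_close = _open_text(source)
    pos = dialect.field_order
    try:
        calls: list[GeneCall] = []
        used: dict[str, int] = {}
        for raw in handle:
            line = raw.rstrip("\n")
            if not line.startswith(">"):
                continue
            header = line[1:].strip()
            fields = header.split(dialect.field_separator)
            if len(fields) != dialect.n_fields:
                raise ValueError(
                    f"expected {dialect.n_fields} fields, got {len(fields)} "
                    f"in header {header!r}"
                )
            strand_token = fields[pos["strand"]]
            if strand_token not in _STRAND_ALIASES:
                raise ValueError(f"unknown strand {strand_token!r} in header {header!r}")
            strand = _STRAND_ALIASES[strand_token]
            low = _parse_coord(fields[pos["low_coord"]], header)
            high = _parse_coord(fields[pos["high_coord"]], header)
            span = dialect.to_halfopen(low, high)
            n_exons = _parse_coord(fields[pos["exon_count"]], header)
            blocks = fields[pos["exon_blocks"]].split(":")
            if len(blocks) != n_exons:
                raise ValueError(
                    f"exon_count {n_exons} != {len(blocks)} exon blocks "
                    f"in header {header!r}"
                )
            exons = []
            for block in blocks:
                lo_s, sep, hi_s = block.partition("-")
                if not sep:
                    raise ValueError(f"malformed exon block {block!r} in header {header!r}")
                exons.append(
                    dialect.to_halfopen(
                        _parse_coord(lo_s, header), _parse_coord(hi_s, header)
                    )
                )
            exons.sort()
            target = fields[pos["target"]]
            n = used.get(target, 0)
            used[target] = n + 1
            gene_id = target if n == 0 else f"{target}.{n}"
            try:
                bitscore = float(fields[pos["bitscore"]])
            except ValueError:
                bitscore = None
            try:
                evalue = float(fields[pos["evalue"]])
            except ValueError:
                evalue = None
            calls.append(
                GeneCall(
                    gene_id=gene_id,
                    contig_id=fields[pos["contig"]],
                    span=span,
                    strand=strand,
                    exons=exons,
                    source_pass="first_pass",
                    score=bitscore,
                    evalue=evalue,
                )
            )
        return GeneSet("metaeuk_headers", calls)
    finally:
        if needs_close:
            handle.close()


def parse_metaeuk_gff(source: TextSource) -> GeneSet:
    """Parse first-pass predictions from GFF3; delegates to the GFF reader."""
    gene_set = read_gff(source)
    return GeneSet(
        "metaeuk_gff",
        [replace(c, source_pass="first_pass") for c in gene_set.calls],
        dict(gene_set.provenance),
    )


def parse_prokaryotic_gff(source: TextSource, flavor: str = "prodigal") -> GeneSet:
    """Parse second-pass (Prodigal/MetaGeneMark-style) GFF3.

    Prokaryotic calls are single-CDS by contract: a grouping attribute
    shared by more than one CDS row is an error.
    """
    if flavor not in ("prodigal", "metagenemark"):
        raise ValueError(f"unknown flavor {flavor!r}")
    gene_set = read_gff(source)
    calls = []
    for call in gene_set.calls:
        if len(call.exons) != 1:
            raise ValueError(
                f"prokaryotic call {call.gene_id!r} has {len(call.exons)} CDS rows; "
                "expected exactly one"
            )
        calls.append(replace(call, source_pass="second_pass"))
    return GeneSet(f"{flavor}_gff", calls, dict(gene_set.provenance))


def clip_to_contigs(
    gene_set: GeneSet, contig_lengths: dict[str, int]
) -> tuple[GeneSet, int]:
    """Clip calls whose coordinates overrun their contig; count the clips.

    Calls on contigs absent from ``contig_lengths`` pass through untouched.
    Clipping to the contig end is conservative for masking (it can only
    shrink the masked region to what exists).
    """
    clipped = 0
    calls = []
    for call in gene_set.calls:
        length = contig_lengths.get(call.contig_id)
        if length is None or call.span.end <= length:
            calls.append(call)
            continue
        if call.span.start >= length:
            clipped += 1
            continue
        exons = [
            Interval(ex.start, min(ex.end, length))
            for ex in call.exons
            if ex.start < length
        ]
        calls.append(
            replace(
                call,
                span=Interval(call.span.start, length),
                exons=exons,
            )
        )
        clipped += 1
    prov = dict(gene_set.provenance)
    if clipped:
        prov["clipped_to_contig"] = str(clipped)
    return GeneSet(gene_set.name, calls, prov), clipped
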