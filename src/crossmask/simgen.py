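"""Seeded synthetic metagenomes with planted genes, and a mock predictor.

The simulator emulates the composition the staged workflow targets:
contigs of i.i.d. intergenic DNA at a chosen GC content, carrying planted
single-CDS prokaryote-like and virus-like genes (start codon, open frame,
terminal stop) and multi-exon eukaryote-like genes whose introns begin GT
and end AG on the coding strand. The truth annotation records exact
coordinates, strands and categories, so every downstream stage — parsers,
masking, the second pass, consolidation, evaluation — can be exercised
end-to-end with no external tools or data.

``degrade_predictions`` turns the truth into a mock first-pass prediction
set with controlled per-category recall (a homology-based first pass
recovers nearly all eukaryotic genes but only a minority of prokaryotic
ones), optional fragmentation into 2-3 sub-calls, and boundary jitter.

All randomness flows from a single integer seed; each operation draws
from its own independent stream, so changing the degrader profile never
perturbs contig composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .predparse import DEFAULT_DIALECT, HeaderDialect
from .orffinder import revcomp
from .seqmodel import ContigRecord, GeneCall, GeneSet, Interval, write_gff

__all__ = [
    "SimConfig",
    "MockPredictorProfile",
    "simulate_metagenome",
    "degrade_predictions",
    "emit_fixture_files",
]

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)
# buffer between planted genes so neighbouring calls never merge or abut
_GENE_SPACING = 30


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-metagenome shape.

    Defaults give 20 contigs of 20-100 kb carrying 200 prokaryote-like, 60
    eukaryote-like and 20 virus-like genes: large enough for stable
    proportions, small enough for seconds-scale runs. Eukaryote-like genes
    have 2-5 exons of 150-450 nt separated by 60-180 nt introns
    (fungal-like scale); prokaryote-like CDS lengths are 300-1500 nt.
    """

    n_contigs: int = 20
    contig_len_range: tuple[int, int] = (20_000, 100_000)
    n_prok_genes: int = 200
    n_euk_genes: int = 60
    n_viral_genes: int = 20
    prok_len_range: tuple[int, int] = (300, 1500)
    euk_exon_count_range: tuple[int, int] = (2, 5)
    euk_exon_len_range: tuple[int, int] = (150, 450)
    intron_len_range: tuple[int, int] = (60, 180)
    gc: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "contig_len_range",
            "prok_len_range",
            "euk_exon_count_range",
            "euk_exon_len_range",
            "intron_len_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} must be an ordered positive range")
        if not (0 < self.gc < 1):
            raise ValueError("gc must be in (0, 1)")
        if self.n_contigs < 1:
            raise ValueError("need at least one contig")
        if self.prok_len_range[0] % 3 or self.prok_len_range[1] % 3:
            raise ValueError("prok_len_range bounds must be multiples of 3")


@dataclass(frozen=True)
class MockPredictorProfile:
    """Degradation profile of a mock predictor run on the truth set.

    ``recall_by_category`` is the chance each true gene of that category is
    recovered at all; ``fragmentation_prob`` the chance a recovered gene is
    split into 2-3 fragments; ``boundary_jitter_nt`` the maximum shift
    applied to outer call boundaries.
    """

    recall_by_category: dict[str, float] = field(
        default_factory=lambda: {"eukaryote": 0.95, "prokaryote": 0.25, "virus": 0.25}
    )
    fragmentation_prob: float = 0.0
    boundary_jitter_nt: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for cat, r in self.recall_by_category.items():
            if not (0 <= r <= 1):
                raise ValueError(f"recall for {cat!r} outside [0, 1]")
        if not (0 <= self.fragmentation_prob <= 1):
            raise ValueError("fragmentation_prob outside [0, 1]")
        if self.boundary_jitter_nt < 0:
            raise ValueError("boundary_jitter_nt must be non-negative")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ATGC", dtype=np.uint8)[
        rng.choice(4, size=n, p=[p[0], p[3], p[1], p[2]])
    ]
    return bases.tobytes().decode("ascii")


def _random_cds(rng: np.random.Generator, length_nt: int) -> str:
    """Start codon + non-stop body codons + one stop; length_nt % 3 == 0."""
    n_codons = length_nt // 3
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    return (
        "ATG"
        + "".join(_SENSE_CODONS[i] for i in body)
        + _STOPS[rng.integers(len(_STOPS))]
    )


def _place(
    rng: np.random.Generator,
    occupied: dict[int, list[tuple[int, int]]],
    contig_lens: list[int],
    gene_len: int,
    max_attempts: int = 200,
) -> tuple[int, int]:
    """Find a (contig index, start) slot leaving _GENE_SPACING around genes."""
    weights = np.array(contig_lens, dtype=float)
    weights /= weights.sum()
    for _ in range(max_attempts):
        ci = int(rng.choice(len(contig_lens), p=weights))
        limit = contig_lens[ci] - gene_len - _GENE_SPACING
        if limit <= _GENE_SPACING:
            continue
        start = int(rng.integers(_GENE_SPACING, limit))
        end = start + gene_len
        if all(
            end + _GENE_SPACING <= s or e + _GENE_SPACING <= start
            for s, e in occupied.get(ci, [])
        ):
            occupied.setdefault(ci, []).append((start, end))
            return ci, start
    raise RuntimeError(
        f"could not place a {gene_len} nt gene after {max_attempts} attempts; "
        "reduce gene counts or enlarge contigs"
    )


def simulate_metagenome(config: SimConfig) -> tuple[list[ContigRecord], GeneSet]:
    """Generate contigs plus an exact truth annotation.

    Same config (and seed) always yields byte-identical contigs and truth.
    Planted genes never overlap one another on a contig.
    """
    rng_seq = _rng(config.seed, 1)
    rng_place = _rng(config.seed, 2)
    rng_gene = _rng(config.seed, 3)

    contig_lens = [
        int(rng_seq.integers(config.contig_len_range[0], config.contig_len_range[1] + 1))
        for _ in range(config.n_contigs)
    ]
    buffers = [
        bytearray(_random_dna(rng_seq, n, config.gc), "ascii") for n in contig_lens
    ]
    occupied: dict[int, list[tuple[int, int]]] = {}
    calls: list[GeneCall] = []

    def plant(gene_seq: str, exon_offsets: list[tuple[int, int]], category: str, idx: int) -> None:
        strand = "+" if rng_gene.random() < 0.5 else "-"
        ci, start = _place(rng_place, occupied, contig_lens, len(gene_seq))
        placed = gene_seq if strand == "+" else revcomp(gene_seq)
        buffers[ci][start : start + len(gene_seq)] = placed.encode("ascii")
        if strand == "+":
            exons = [Interval(start + s, start + e) for s, e in exon_offsets]
        else:
            L = len(gene_seq)
            exons = sorted(
                Interval(start + L - e, start + L - s) for s, e in exon_offsets
            )
        calls.append(
            GeneCall(
                gene_id=f"{category[:3]}_{idx:04d}",
                contig_id=f"contig_{ci + 1:03d}",
                span=Interval(start, start + len(gene_seq)),
                strand=strand,
                exons=exons,
                source_pass="truth",
                category=category,
            )
        )

    for idx, category in (
        *((i, "prokaryote") for i in range(config.n_prok_genes)),
        *((i, "virus") for i in range(config.n_viral_genes)),
    ):
        lo, hi = config.prok_len_range
        length = 3 * int(rng_gene.integers(lo // 3, hi // 3 + 1))
        cds = _random_cds(rng_gene, length)
        plant(cds, [(0, length)], category, idx)

    for idx in range(config.n_euk_genes):
        k = int(rng_gene.integers(*config.euk_exon_count_range, endpoint=True))
        exon_lens = [
            int(rng_gene.integers(*config.euk_exon_len_range, endpoint=True))
            for _ in range(k)
        ]
        total = sum(exon_lens)
        exon_lens[-1] += (3 - total % 3) % 3  # CDS length must be a codon multiple
        cds = _random_cds(rng_gene, sum(exon_lens))
        parts: list[str] = []
        exon_offsets: list[tuple[int, int]] = []
        cds_pos = 0
        gene_pos = 0
        for j, elen in enumerate(exon_lens):
            parts.append(cds[cds_pos : cds_pos + elen])
            exon_offsets.append((gene_pos, gene_pos + elen))
            cds_pos += elen
            gene_pos += elen
            if j < k - 1:
                ilen = int(rng_gene.integers(*config.intron_len_range, endpoint=True))
                intron = "GT" + _random_dna(rng_gene, ilen - 4, config.gc) + "AG"
                parts.append(intron)
                gene_pos += ilen
        plant("".join(parts), exon_offsets, "eukaryote", idx)

    contigs = [
        ContigRecord(f"contig_{i + 1:03d}", buf.decode("ascii"))
        for i, buf in enumerate(buffers)
    ]
    calls.sort(key=lambda c: (c.contig_id, c.span.start, c.strand))
    truth = GeneSet(
        "truth",
        calls,
        {"generator": "crossmask.simgen", "seed": str(config.seed)},
    )
    return contigs, truth


def _fragment_call(
    call: GeneCall, rng: np.random.Generator, n_frags: int
) -> list[GeneCall]:
    """Split a call into contiguous coding-coordinate chunks within its exons."""
    total = call.coding_length
    min_chunk = 30
    if total < n_frags * min_chunk:
        return [call]
    cuts = sorted(
        int(rng.integers(min_chunk, total - min_chunk + 1)) for _ in range(n_frags - 1)
    )
    bounds = [0, *cuts, total]
    if any(b2 - b1 < min_chunk for b1, b2 in zip(bounds, bounds[1:])):
        return [call]
    frags = []
    for fi, (lo, hi) in enumerate(zip(bounds, bounds[1:]), start=1):
        # map coding-coordinate [lo, hi) back onto genomic exon pieces
        exons = []
        pos = 0
        for ex in call.exons:
            ex_lo, ex_hi = pos, pos + len(ex)
            a, b = max(lo, ex_lo), min(hi, ex_hi)
            if a < b:
                exons.append(Interval(ex.start + (a - ex_lo), ex.start + (b - ex_lo)))
            pos = ex_hi
        frags.append(
            replace(
                call,
                gene_id=f"{call.gene_id}.f{fi}",
                span=Interval(exons[0].start, exons[-1].end),
                exons=exons,
            )
        )
    return frags


def degrade_predictions(
    truth: GeneSet,
    profile: MockPredictorProfile,
    contig_lengths: dict[str, int] | None = None,
) -> GeneSet:
    """Derive a mock prediction set from the truth annotation.

    Each truth call survives independently with its category's recall;
    survivors may be fragmented and have their outer boundaries jittered
    (never across contig bounds when lengths are supplied, never past
    position 0, and never so far that an exon empties). Output calls are
    tagged ``source_pass="first_pass"``.
    """
    rng = _rng(profile.seed, 11)
    out: list[GeneCall] = []
    for call in truth.calls:
        recall = profile.recall_by_category.get(call.category, 1.0)
        if rng.random() >= recall:
            continue
        pieces = [call]
        if profile.fragmentation_prob and rng.random() < profile.fragmentation_prob:
            pieces = _fragment_call(call, rng, int(rng.integers(2, 4)))
        for piece in pieces:
            exons = [Interval(ex.start, ex.end) for ex in piece.exons]
            j = profile.boundary_jitter_nt
            if j:
                limit = None if contig_lengths is None else contig_lengths.get(piece.contig_id)
                first, last = exons[0], exons[-1]
                ds = int(rng.integers(-j, j + 1))
                de = int(rng.integers(-j, j + 1))
                new_start = min(max(0, first.start + ds), first.end - 1)
                new_end = max(last.start + 1, last.end + de)
                if limit is not None:
                    new_end = min(new_end, limit)
                exons[0] = Interval(new_start, first.end)
                if len(exons) == 1:
                    exons[0] = Interval(new_start, max(new_start + 1, new_end))
                else:
                    exons[-1] = Interval(last.start, new_end)
            out.append(
                replace(
                    piece,
                    source_pass="first_pass",
                    span=Interval(exons[0].start, exons[-1].end),
                    exons=exons,
                )
            )
    return GeneSet(
        "mock_first_pass",
        out,
        {
            "generator": "crossmask.simgen.degrade_predictions",
            "seed": str(profile.seed),
        },
    )


def emit_fixture_files(
    gene_set: GeneSet,
    format: str,
    dialect: HeaderDialect = DEFAULT_DIALECT,
) -> str:
    """Render a GeneSet in one of the dialects the parsers consume.

    Formats: "metaeuk_headers" (predictions FASTA whose headers carry the
    coordinates), "metaeuk_gff", or "prokaryotic_gff" (single-CDS rows,
    Prodigal-like). ``parse(emit(x))`` reproduces contig, span, strand and
    exons exactly.
    """
    if format == "metaeuk_gff":
        return write_gff(gene_set)
    if format == "prokaryotic_gff":
        lines = ["##gff-version 3"]
        for call in gene_set.calls:
            if len(call.exons) != 1:
                raise ValueError(
                    f"call {call.gene_id!r} has {len(call.exons)} exons; "
                    "prokaryotic GFF requires single-CDS calls"
                )
            lines.append(
                "\t".join(
                    [
                        call.contig_id,
                        "mock_prodigal",
                        "CDS",
                        str(call.span.start + 1),
                        str(call.span.end),
                        "." if call.score is None else format_score(call.score),
                        call.strand,
                        "0",
                        f"ID={call.gene_id}",
                    ]
                )
            )
        return "\n".join(lines) + "\n"
    if format == "metaeuk_headers":
        pos = dialect.field_order
        lines = []
        for call in gene_set.calls:
            low, high = dialect.from_halfopen(call.span)
            blocks = ":".join(
                "{}-{}".format(*dialect.from_halfopen(ex)) for ex in call.exons
            )
            fields = [""] * dialect.n_fields
            fields[pos["target"]] = call.gene_id
            fields[pos["contig"]] = call.contig_id
            fields[pos["strand"]] = call.strand
            fields[pos["bitscore"]] = (
                "0" if call.score is None else format_score(call.score)
            )
            fields[pos["evalue"]] = (
                "0" if call.evalue is None else format_score(call.evalue)
            )
            fields[pos["exon_count"]] = str(len(call.exons))
            fields[pos["low_coord"]] = str(low)
            fields[pos["high_coord"]] = str(high)
            fields[pos["exon_blocks"]] = blocks
            lines.append(">" + dialect.field_separator.join(fields))
            lines.append("N")  # body placeholder; parsers ignore it
        return "\n".join(lines) + ("\n" if lines else "")
    raise ValueError(f"unknown fixture format {format!r}")


def format_score(x: float) -> str:
    return format(x, "g")
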