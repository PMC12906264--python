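"""Naive six-frame ORF caller.

A deliberately simple, deterministic stand-in for a prokaryotic gene
predictor: scan all six reading frames, and for every stop codon report
the ORF running from the furthest-upstream in-frame start codon (after the
previous in-frame stop) through the stop codon inclusive, provided it
reaches the minimum length. No statistical gene model, no partial
(edge-truncated) calls.

Because a codon containing 'N' can be neither start nor stop and (by
default) disqualifies any ORF containing it, this caller never calls
genes inside hard-masked regions — the property that makes the staged
workflow's second pass non-redundant with the first.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqmodel import ContigRecord, GeneCall, GeneSet, Interval, IUPAC_DNA

__all__ = ["OrfParams", "find_orfs", "revcomp"]

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
}
_REVCOMP_TABLE = str.maketrans(
    {**_COMPLEMENT, **{k.lower(): v.lower() for k, v in _COMPLEMENT.items()}}
)


def revcomp(seq: str) -> str:
    """IUPAC-aware reverse complement (case preserved; involution)."""
    for pos, ch in enumerate(seq):
        if ch.upper() not in IUPAC_DNA:
            raise ValueError(f"non-IUPAC character {ch!r} at position {pos}")
    return seq.translate(_REVCOMP_TABLE)[::-1]


@dataclass(frozen=True)
class OrfParams:
    """ORF-calling thresholds.

    ``min_len_nt`` includes the stop codon. The default 300 nt (100
    codons) is the classic conservative naive-ORF cutoff: the surrogate
    should under-call, not over-call, relative to real predictors. Start
    set follows the bacterial code (ATG/GTG/TTG).
    """

    min_len_nt: int = 300
    start_codons: frozenset[str] = frozenset({"ATG", "GTG", "TTG"})
    stop_codons: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})
    both_strands: bool = True
    allow_ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.min_len_nt < 6 or self.min_len_nt % 3 != 0:
            raise ValueError("min_len_nt must be >= 6 and a multiple of 3")
        if self.start_codons & self.stop_codons:
            raise ValueError("start and stop codon sets must be disjoint")
        object.__setattr__(self, "start_codons", frozenset(self.start_codons))
        object.__setattr__(self, "stop_codons", frozenset(self.stop_codons))


def _scan_strand(seq: str, params: OrfParams) -> list[tuple[int, int]]:
    """Single-strand scan; returns stop-inclusive [start, end) pairs."""
    n = len(seq)
    orfs: list[tuple[int, int]] = []
    acgt = frozenset("ACGT")
    for frame in range(3):
        cur_start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if not (set(codon) <= acgt):
                if not params.allow_ambiguous:
                    # an ambiguous codon disqualifies any ORF containing it
                    cur_start = None
                continue
            if codon in params.stop_codons:
                if cur_start is not None and (i + 3) - cur_start >= params.min_len_nt:
                    orfs.append((cur_start, i + 3))
                cur_start = None
            elif codon in params.start_codons and cur_start is None:
                cur_start = i
    return orfs


def find_orfs(contig: ContigRecord, params: OrfParams = OrfParams()) -> GeneSet:
    """Call ORFs on one contig, both strands by default.

    Minus-strand ORFs are reported in forward-strand coordinates (so they
    can be masked and compared directly). Calls are single-exon, tagged
    ``source_pass="fallback"``, and ordered by (start, end, strand) with
    ids ``<contig>_orf<k>``.
    """
    upper = contig.seq.upper()
    found: list[tuple[int, int, str]] = [
        (s, e, "+") for s, e in _scan_strand(upper, params)
    ]
    if params.both_strands:
        n = len(upper)
        rc = revcomp(upper)
        found.extend((n - e, n - s, "-") for s, e in _scan_strand(rc, params))
    found.sort()
    calls = [
        GeneCall(
            gene_id=f"{contig.id}_orf{k}",
            contig_id=contig.id,
            span=Interval(s, e),
            strand=strand,
            exons=[Interval(s, e)],
            source_pass="fallback",
        )
        for k, (s, e, strand) in enumerate(found, start=1)
    ]
    return GeneSet(f"orfs_{contig.id}", calls)
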