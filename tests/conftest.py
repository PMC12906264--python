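"""Shared fixtures and random-instance builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from crossmask.seqmodel import ContigRecord, GeneCall, GeneSet, Interval


def random_dna(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


def random_intervals(
    rng: np.random.Generator, length: int, n: int, max_len: int = 40
) -> list[Interval]:
    """Arbitrary intervals within [0, length): may nest, touch, duplicate."""
    out = []
    for _ in range(n):
        start = int(rng.integers(0, length - 1))
        end = int(rng.integers(start + 1, min(length, start + max_len) + 1))
        out.append(Interval(start, end))
    return out


def random_gene_set(
    rng: np.random.Generator,
    contig_lengths: dict[str, int],
    n_calls: int,
    multi_exon: bool = True,
    name: str = "random",
) -> GeneSet:
    """Random valid calls (non-overlapping exons within each call only)."""
    calls = []
    contig_ids = sorted(contig_lengths)
    for k in range(n_calls):
        contig_id = contig_ids[int(rng.integers(len(contig_ids)))]
        length = contig_lengths[contig_id]
        n_exons = int(rng.integers(1, 4)) if multi_exon else 1
        start = int(rng.integers(0, max(1, length - 600)))
        exons = []
        pos = start
        for _ in range(n_exons):
            ex_len = int(rng.integers(10, 120))
            end = min(pos + ex_len, length)
            if end <= pos:
                break
            exons.append(Interval(pos, end))
            pos = end + int(rng.integers(5, 60))
            if pos >= length:
                break
        if not exons:
            exons = [Interval(start, start + 1)]
        calls.append(
            GeneCall(
                gene_id=f"g{k}",
                contig_id=contig_id,
                span=Interval(exons[0].start, exons[-1].end),
                strand="+" if rng.random() < 0.5 else "-",
                exons=exons,
                score=float(np.round(rng.random() * 100, 2)),
                evalue=float(10.0 ** -int(rng.integers(0, 30))),
            )
        )
    return GeneSet(name, calls)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture
def small_contig() -> ContigRecord:
    return ContigRecord("ctg", "ACGTACGTACGTACGTACGT")
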