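"""Synthetic metagenome generator and mock predictor degrader.

Planted-gene validity is checked by re-scanning the emitted sequences,
not by trusting the generator's own bookkeeping.
"""

import io
from dataclasses import replace

import pytest
from scipy import stats as scistats

from crossmask.orffinder import revcomp
from crossmask.predparse import parse_metaeuk_headers, parse_prokaryotic_gff
from crossmask.seqmodel import GeneCall, GeneSet, Interval, write_fasta
from crossmask.simgen import (
    MockPredictorProfile,
    SimConfig,
    degrade_predictions,
    emit_fixture_files,
    simulate_metagenome,
)

SMALL = SimConfig(
    n_contigs=3,
    contig_len_range=(15_000, 25_000),
    n_prok_genes=15,
    n_euk_genes=6,
    n_viral_genes=3,
    seed=7,
)

STOPS = {"TAA", "TAG", "TGA"}


def coding_sequence(call: GeneCall, seq_by_contig: dict[str, str]) -> str:
    seq = seq_by_contig[call.contig_id]
    cds = "".join(seq[ex.start : ex.end] for ex in call.exons)
    return revcomp(cds) if call.strand == "-" else cds


class TestSimulateMetagenome:
    def test_determinism_and_counts(self):
        contigs1, truth1 = simulate_metagenome(SMALL)
        contigs2, truth2 = simulate_metagenome(SMALL)
        assert len(contigs1) == 3
        assert write_fasta(contigs1) == write_fasta(contigs2)
        assert [c.gene_id for c in truth1.calls] == [c.gene_id for c in truth2.calls]
        assert len(truth1) == 15 + 6 + 3

    def test_different_seed_differs(self):
        contigs1, _ = simulate_metagenome(SMALL)
        contigs2, _ = simulate_metagenome(replace(SMALL, seed=8))
        assert write_fasta(contigs1) != write_fasta(contigs2)

    def test_planted_single_cds_genes_rescanned(self):
        contigs, truth = simulate_metagenome(SMALL)
        seqs = {c.id: c.seq for c in contigs}
        checked = 0
        for call in truth.calls:
            if call.category == "eukaryote":
                continue
            cds = coding_sequence(call, seqs)
            codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
            assert codons[0] == "ATG"
            assert codons[-1] in STOPS
            assert not any(c in STOPS for c in codons[:-1])
            assert len(call.exons) == 1 and call.exons[0] == call.span
            checked += 1
        assert checked == 18

    def test_eukaryote_genes_spliced_correctly(self):
        contigs, truth = simulate_metagenome(SMALL)
        seqs = {c.id: c.seq for c in contigs}
        checked = 0
        for call in truth.calls:
            if call.category != "eukaryote":
                continue
            cds = coding_sequence(call, seqs)
            assert len(cds) % 3 == 0
            codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
            assert codons[0] == "ATG" and codons[-1] in STOPS
            assert not any(c in STOPS for c in codons[:-1])
            # introns carry GT..AG on the coding strand
            seq = seqs[call.contig_id]
            gaps = [
                seq[a.end : b.start] for a, b in zip(call.exons, call.exons[1:])
            ]
            if call.strand == "-":
                gaps = [revcomp(g) for g in reversed(gaps)]
            for intron in gaps:
                assert intron[:2] == "GT" and intron[-2:] == "AG"
            checked += 1
        assert checked == 6

    def test_planted_genes_do_not_overlap(self):
        _, truth = simulate_metagenome(SMALL)
        by_contig = {}
        for call in truth.calls:
            by_contig.setdefault(call.contig_id, []).append(call.span)
        for spans in by_contig.values():
            spans.sort()
            for a, b in zip(spans, spans[1:]):
                assert a.end <= b.start

    def test_infeasible_packing_raises(self):
        config = SimConfig(
            n_contigs=1,
            contig_len_range=(2_000, 2_000),
            n_prok_genes=40,
            n_euk_genes=0,
            n_viral_genes=0,
            prok_len_range=(900, 900),
            seed=1,
        )
        with pytest.raises(RuntimeError, match="place"):
            simulate_metagenome(config)


class TestDegradePredictions:
    def test_perfect_profile_is_identity_on_coordinates(self):
        _, truth = simulate_metagenome(SMALL)
        profile = MockPredictorProfile(
            recall_by_category={"eukaryote": 1.0, "prokaryote": 1.0, "virus": 1.0},
            fragmentation_prob=0.0,
            boundary_jitter_nt=0,
            seed=1,
        )
        pred = degrade_predictions(truth, profile)
        assert [(c.contig_id, c.span, c.strand, c.exons) for c in pred.calls] == [
            (c.contig_id, c.span, c.strand, c.exons) for c in truth.calls
        ]
        assert all(c.source_pass == "first_pass" for c in pred.calls)

    def test_zero_recall_empties(self):
        _, truth = simulate_metagenome(SMALL)
        profile = MockPredictorProfile(
            recall_by_category={"eukaryote": 0.0, "prokaryote": 0.0, "virus": 0.0},
            seed=1,
        )
        assert len(degrade_predictions(truth, profile)) == 0

    def test_kept_count_within_binomial_bounds(self):
        truth = GeneSet(
            "t",
            [
                GeneCall(
                    f"g{i}", "c", Interval(i * 500, i * 500 + 300), "+",
                    [Interval(i * 500, i * 500 + 300)],
                    source_pass="truth", category="prokaryote",
                )
                for i in range(400)
            ],
        )
        lo, hi = scistats.binom.interval(0.999, 400, 0.25)
        profile = MockPredictorProfile(
            recall_by_category={"prokaryote": 0.25}, seed=42
        )
        kept = len(degrade_predictions(truth, profile))
        assert lo <= kept <= hi

    def test_fragments_stay_within_parent_exons(self):
        _, truth = simulate_metagenome(SMALL)
        profile = MockPredictorProfile(
            recall_by_category={"eukaryote": 1.0, "prokaryote": 1.0, "virus": 1.0},
            fragmentation_prob=1.0,
            seed=3,
        )
        pred = degrade_predictions(truth, profile)
        assert len(pred) > len(truth)  # fragmentation increased the count
        parents = {c.gene_id: c for c in truth.calls}
        for call in pred.calls:
            parent = parents[call.gene_id.split(".f")[0]]
            for ex in call.exons:
                assert any(p.start <= ex.start and ex.end <= p.end for p in parent.exons)

    def test_jitter_respects_bounds(self):
        contigs, truth = simulate_metagenome(SMALL)
        lengths = {c.id: len(c.seq) for c in contigs}
        profile = MockPredictorProfile(
            recall_by_category={"eukaryote": 1.0, "prokaryote": 1.0, "virus": 1.0},
            boundary_jitter_nt=25,
            seed=9,
        )
        pred = degrade_predictions(truth, profile, lengths)
        for call in pred.calls:
            assert 0 <= call.span.start < call.span.end <= lengths[call.contig_id]


class TestEmitFixtureFiles:
    def test_headers_round_trip(self):
        _, truth = simulate_metagenome(SMALL)
        text = emit_fixture_files(truth, "metaeuk_headers")
        assert text.count(">") == len(truth)
        back = parse_metaeuk_headers(io.StringIO(text))
        for orig, rt in zip(truth.calls, back.calls):
            assert (rt.contig_id, rt.span, rt.strand, rt.exons) == (
                orig.contig_id, orig.span, orig.strand, orig.exons
            )

    def test_empty_set_emits_empty_or_header_only(self):
        assert emit_fixture_files(GeneSet("e"), "metaeuk_headers") == ""
        assert emit_fixture_files(GeneSet("e"), "metaeuk_gff") == "##gff-version 3\n"

    def test_prokaryotic_gff_round_trip_and_multi_exon_error(self):
        _, truth = simulate_metagenome(SMALL)
        prok = GeneSet("prok", [c for c in truth.calls if len(c.exons) == 1])
        back = parse_prokaryotic_gff(io.StringIO(emit_fixture_files(prok, "prokaryotic_gff")))
        assert [(c.contig_id, c.span, c.strand) for c in back.calls] == [
            (c.contig_id, c.span, c.strand) for c in prok.calls
        ]
        with pytest.raises(ValueError, match="single-CDS"):
            emit_fixture_files(truth, "prokaryotic_gff")
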