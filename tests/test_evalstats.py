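"""Summaries, truth comparison, translation, alignment identity."""

import math

import numpy as np
import pytest

from crossmask.evalstats import (
    AlignScoring,
    compare_to_truth,
    label_by_truth,
    percent_identity,
    summarize,
    translate_cds,
)
from crossmask.orffinder import revcomp
from crossmask.seqmodel import ContigRecord, GeneCall, GeneSet, Interval

from conftest import random_gene_set


def single_exon(gene_id, start, end, strand="+", contig="c", **kw):
    return GeneCall(gene_id, contig, Interval(start, end), strand, [Interval(start, end)], **kw)


class TestSummarize:
    def test_mean_and_total(self):
        gs = GeneSet("s", [single_exon("a", 0, 300), single_exon("b", 400, 1000)])
        row = summarize(gs)[0]
        assert (row.n_genes, row.mean_len_nt, row.total_len_nt) == (2, 450.0, 900)
        assert row.median_len_nt == 300.0  # lower middle for even counts

    def test_empty_set_gives_zero_row(self):
        row = summarize(GeneSet("s"))[0]
        assert row.n_genes == 0 and row.total_len_nt == 0
        assert math.isnan(row.mean_len_nt)

    def test_grouping_partitions_counts(self, rng):
        gs = random_gene_set(rng, {"c": 5000}, 40)
        calls = [
            GeneCall(
                c.gene_id, c.contig_id, c.span, c.strand, c.exons,
                source_pass=("first_pass", "second_pass")[i % 2],
                category=("eukaryote", "prokaryote", "virus")[i % 3],
            )
            for i, c in enumerate(gs.calls)
        ]
        gs = GeneSet("mixed", calls)
        for group_by in ("category", "source_pass"):
            rows = summarize(gs, group_by=group_by)
            assert sum(r.n_genes for r in rows) == len(gs)

    def test_coding_length_not_span_length(self):
        call = GeneCall("g", "c", Interval(0, 100), "+", [Interval(0, 30), Interval(70, 100)])
        assert summarize(GeneSet("s", [call]))[0].total_len_nt == 60


class TestCompareToTruth:
    def test_identical_sets(self):
        truth = GeneSet("t", [single_exon("a", 0, 300), single_exon("b", 400, 700)])
        pred = GeneSet("p", [single_exon("pa", 0, 300), single_exon("pb", 400, 700)])
        rep = compare_to_truth(pred, truth)
        assert (rep.sensitivity, rep.fragmentation, rep.mean_len_ratio) == (1.0, 1.0, 1.0)

    def test_three_fragments_detected_and_counted(self):
        truth = GeneSet("t", [single_exon("g", 0, 900)])
        pred = GeneSet(
            "p",
            [single_exon("f1", 0, 300), single_exon("f2", 300, 600), single_exon("f3", 600, 900)],
        )
        rep = compare_to_truth(pred, truth)
        assert rep.detected == 1
        assert rep.fragmentation == 3.0

    def test_below_overlap_frac_not_detected(self):
        truth = GeneSet("t", [single_exon("g", 0, 1000)])
        pred = GeneSet("p", [single_exon("f", 0, 400)])
        assert compare_to_truth(pred, truth).detected == 0
        assert compare_to_truth(pred, truth, overlap_frac=0.3).detected == 1

    def test_strand_awareness(self):
        truth = GeneSet("t", [single_exon("g", 0, 300, strand="+")])
        pred = GeneSet("p", [single_exon("f", 0, 300, strand="-")])
        assert compare_to_truth(pred, truth).detected == 0
        assert compare_to_truth(pred, truth, strand_aware=False).detected == 1

    def test_overlap_frac_out_of_range(self):
        with pytest.raises(ValueError):
            compare_to_truth(GeneSet("p"), GeneSet("t"), overlap_frac=0.0)

    def test_detected_matches_per_base_coverage_oracle(self, rng):
        for trial in range(30):
            truth = random_gene_set(rng, {"c": 3000}, 8, name=f"t{trial}")
            pred = random_gene_set(rng, {"c": 3000}, 12, name=f"p{trial}")
            rep = compare_to_truth(pred, truth, overlap_frac=0.5)
            expected = 0
            for t in truth.calls:
                cover = np.zeros(3000, dtype=bool)
                for p in pred.calls:
                    if p.strand != t.strand:
                        continue
                    for ex in p.exons:
                        cover[ex.start : ex.end] = True
                got = sum(int(cover[ex.start : ex.end].sum()) for ex in t.exons)
                if got >= 0.5 * t.coding_length:
                    expected += 1
            assert rep.detected == expected


class TestTranslateCds:
    def test_plus_strand(self):
        contig = ContigRecord("c", "ATGAAATAA")
        assert translate_cds(single_exon("g", 0, 9), contig) == "MK"

    def test_minus_strand_symmetry(self):
        contig = ContigRecord("c", revcomp("ATGAAATAA"))
        assert translate_cds(single_exon("g", 0, 9, strand="-"), contig) == "MK"

    def test_alternative_start_becomes_m(self):
        contig = ContigRecord("c", "GTGAAATAA")
        assert translate_cds(single_exon("g", 0, 9), contig) == "MK"

    def test_non_codon_multiple_raises(self):
        contig = ContigRecord("c", "ATGAAATA")
        with pytest.raises(ValueError, match="multiple of 3"):
            translate_cds(single_exon("g", 0, 8), contig)

    def test_internal_stop_raises_unless_partial(self):
        contig = ContigRecord("c", "ATGTAAAAATAA")
        call = single_exon("g", 0, 12)
        with pytest.raises(ValueError, match="internal stop"):
            translate_cds(call, contig)
        assert translate_cds(call, contig, partial_ok=True) == "M*K"

    def test_spliced_cds(self):
        # exon1 ATGAAA, intron GTxxAG, exon2 TGA  (case ignored)
        contig = ContigRecord("c", "ATGAAAgtTTagTGA")
        call = GeneCall(
            "g", "c", Interval(0, 15), "+", [Interval(0, 6), Interval(12, 15)]
        )
        assert translate_cds(call, contig) == "MK"


class TestPercentIdentity:
    def test_identity_and_symmetry(self):
        assert percent_identity("MKV", "MKV") == 100.0
        assert percent_identity("MKV", "MKL") == pytest.approx(200 / 3)
        assert percent_identity("MKVTTA", "MKL") == pytest.approx(
            percent_identity("MKL", "MKVTTA")
        )

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            percent_identity("", "MK")

    def test_scoring_validation(self):
        with pytest.raises(ValueError):
            AlignScoring(match=1.0, mismatch=2.0)
        with pytest.raises(ValueError):
            AlignScoring(gap=0.0)

    def test_bounded(self, rng):
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(50):
            a = "".join(alphabet[i] for i in rng.integers(0, 20, size=int(rng.integers(1, 12))))
            b = "".join(alphabet[i] for i in rng.integers(0, 20, size=int(rng.integers(1, 12))))
            pid = percent_identity(a, b)
            assert 0.0 <= pid <= 100.0
            assert pid == pytest.approx(percent_identity(b, a))


class TestLabelByTruth:
    def test_categories_transfer_by_overlap(self):
        truth = GeneSet("t", [single_exon("t1", 0, 300, category="prokaryote")])
        pred = GeneSet("p", [single_exon("p1", 50, 350), single_exon("p2", 1000, 1300)])
        labeled = label_by_truth(pred, truth)
        assert labeled.calls[0].category == "prokaryote"
        assert labeled.calls[1].category == "unknown"
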