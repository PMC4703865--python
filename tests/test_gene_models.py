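"""Annotation parsing, primary-transcript selection and window derivation."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pausekit.gene_models import (
    AnnotationError,
    GenomicInterval,
    TranscriptModel,
    derive_windows,
    gene_spans,
    parse_annotation,
    select_primary_transcript,
    transcripts_to_gtf,
    windows_to_bed,
)

GTF_LINE = 'chr1\t.\ttranscript\t1001\t3000\t.\t{strand}\t.\tgene_id "G1"; transcript_id "{tx}";\n'


class TestParseAnnotation:
    def test_coordinate_conversion_and_tss(self):
        models = parse_annotation(io.StringIO(GTF_LINE.format(strand="+", tx="T1")))
        (t,) = models["G1"]
        assert (t.tx_start, t.tx_end, t.tss, t.strand) == (1000, 3000, 1000, "+")

    def test_minus_strand_tss_is_three_prime_end_of_span(self):
        models = parse_annotation(io.StringIO(GTF_LINE.format(strand="-", tx="T1")))
        assert models["G1"][0].tss == 2999

    def test_two_transcripts_grouped_under_one_gene(self):
        text = GTF_LINE.format(strand="+", tx="T1") + GTF_LINE.format(strand="+", tx="T2")
        models = parse_annotation(io.StringIO(text))
        assert [t.transcript_id for t in models["G1"]] == ["T1", "T2"]

    def test_malformed_line_error_names_line_number(self):
        text = GTF_LINE.format(strand="+", tx="T1") + "chr1\tonly three\tfields\n"
        with pytest.raises(AnnotationError, match="line 2"):
            parse_annotation(io.StringIO(text))

    def test_inverted_span_rejected_with_warning(self):
        bad = 'chr1\t.\ttranscript\t3000\t1001\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
        with pytest.warns(UserWarning, match="rejected"):
            models = parse_annotation(io.StringIO(bad))
        assert models == {}

    def test_non_coding_biotype_filtered(self):
        line = (
            'chr1\t.\ttranscript\t1\t500\t.\t+\t.\t'
            'gene_id "G2"; transcript_id "T9"; gene_biotype "lincRNA";\n'
        )
        assert parse_annotation(io.StringIO(line)) == {}
        assert "G2" in parse_annotation(io.StringIO(line), protein_coding_only=False)

    def test_round_trip_is_identity(self):
        text = GTF_LINE.format(strand="+", tx="T1") + GTF_LINE.format(strand="-", tx="T2")
        models = parse_annotation(io.StringIO(text))
        again = parse_annotation(io.StringIO(transcripts_to_gtf(models["G1"])))
        assert again == models


class TestPrimarySelection:
    def _gene(self, *lengths):
        return [
            TranscriptModel("G", f"T{i}", "chr1", "+", 0, length)
            for i, length in enumerate(lengths, start=1)
        ]

    def test_argmax_density(self):
        assert select_primary_transcript(self._gene(1000, 1000), {"T1": 0.4, "T2": 0.1}) == "T1"

    def test_tie_broken_by_length_then_id(self):
        # T2 longer wins the density tie
        assert select_primary_transcript(self._gene(1000, 2000), {"T1": 0.2, "T2": 0.2}) == "T2"
        # equal density and length: lexicographically smaller id
        assert select_primary_transcript(self._gene(1000, 1000), {"T1": 0.2, "T2": 0.2}) == "T1"
        assert (
            select_primary_transcript(self._gene(1000, 1000, 1000), {"T1": 0.0, "T2": 0.0, "T3": 0.0})
            == "T1"
        )

    def test_single_transcript_and_empty(self):
        assert select_primary_transcript(self._gene(1000), {"T1": 0.0}) == "T1"
        with pytest.raises(ValueError):
            select_primary_transcript([], {})


class TestDeriveWindows:
    def test_plus_strand_arithmetic(self):
        t = TranscriptModel("G", "T", "chr1", "+", 10_000, 15_000)
        ws = derive_windows(t)
        assert ws.tss_window == GenomicInterval("chr1", 9_850, 10_150)
        assert ws.body_window == GenomicInterval("chr1", 10_250, 15_000)
        assert ws.body_length == 4_750
        assert ws.flank_window == GenomicInterval("chr1", 8_000, 12_500)
        assert ws.body_valid

    def test_minus_strand_matches_mirror_oracle(self):
        t = TranscriptModel("G", "T", "chr1", "-", 10_000, 15_001)
        ws = derive_windows(t)
        assert t.tss == 15_000
        assert ws.tss_window == GenomicInterval("chr1", 14_851, 15_151)
        assert ws.body_window == GenomicInterval("chr1", 10_000, 14_751)

    def test_short_transcript_body_flagged(self):
        t = TranscriptModel("G", "T", "chr1", "+", 0, 300)
        ws = derive_windows(t)
        assert not ws.body_valid
        t2 = TranscriptModel("G", "T", "chr1", "+", 0, 449)
        assert not derive_windows(t2).body_valid
        t3 = TranscriptModel("G", "T", "chr1", "+", 0, 450)
        assert derive_windows(t3).body_valid

    def test_window_lengths_fixed_away_from_edges(self):
        t = TranscriptModel("G", "T", "chr1", "-", 50_000, 53_000)
        ws = derive_windows(t)
        assert len(ws.tss_window) == 300
        assert len(ws.flank_window) == 4_500

    def test_clipping_at_chromosome_start(self):
        t = TranscriptModel("G", "T", "chr1", "+", 100, 5_000)
        ws = derive_windows(t)
        assert ws.tss_window.start == 0
        assert ws.flank_window.start == 0

    @settings(derandomize=True, max_examples=60)
    @given(
        start=st.integers(min_value=5_000, max_value=200_000),
        length=st.integers(min_value=600, max_value=50_000),
        strand=st.sampled_from(["+", "-"]),
        pivot=st.integers(min_value=500_000, max_value=1_000_000),
    )
    def test_strand_mirror_symmetry(self, start, length, strand, pivot):
        """Reflecting coordinates and flipping strand reflects all windows."""

        def reflect(iv):
            return GenomicInterval(iv.chrom, pivot - iv.end + 1, pivot - iv.start + 1)

        t = TranscriptModel("G", "T", "chr1", strand, start, start + length)
        flipped = TranscriptModel(
            "G", "T", "chr1", "-" if strand == "+" else "+",
            pivot - t.tx_end + 1, pivot - t.tx_start + 1,
        )
        ws, mirrored = derive_windows(t), derive_windows(flipped)
        assert mirrored.tss_window == reflect(ws.tss_window)
        assert mirrored.flank_window == reflect(ws.flank_window)
        assert (ws.body_window is None) == (mirrored.body_window is None)
        if ws.body_window is not None:
            assert mirrored.body_window == reflect(ws.body_window)
        assert mirrored.body_length == ws.body_length


def test_gene_spans_union_and_bed_export():
    t1 = TranscriptModel("G", "T1", "chr1", "+", 1_000, 5_000)
    t2 = TranscriptModel("G", "T2", "chr1", "+", 2_000, 9_000)
    spans = gene_spans({"G": [t1, t2]})
    assert spans["G"] == GenomicInterval("chr1", 1_000, 9_000)
    bed = windows_to_bed([derive_windows(t1)])
    lines = [l.split("\t") for l in bed.strip().splitlines()]
    assert [l[3] for l in lines] == ["G|T1|tss", "G|T1|body", "G|T1|flank"]
    assert all(l[5] == "+" for l in lines)
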