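"""Read loading, assignment oracle equivalence, scaling and profiles."""

import numpy as np
import pytest

from pausekit import coverage
from pausekit.coverage import ReadRecord, assign_reads, library_scale_factors, load_reads
from pausekit.gene_models import GenomicInterval, TranscriptModel, derive_windows

from conftest import brute_force_assign, pileup_mean_depth, random_gene_fixture, random_reads


class TestLoadReads:
    def test_bed_fixture(self, tmp_path):
        p = tmp_path / "reads.bed"
        p.write_text("chr1\t10\t46\nchr1\t100\t136\t.\t0\t-\nchr2\t5\t41\n")
        rs = load_reads(p)
        assert rs.total_mapped_reads == 3
        assert rs.reads[1] == ReadRecord("chr1", 100, 136, "-")

    def test_empty_file_errors_at_scaling(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        rs = load_reads(p)
        assert rs.total_mapped_reads == 0
        with pytest.raises(ValueError):
            library_scale_factors({"lib": rs.total_mapped_reads})

    def test_invalid_interval_skipped_and_counted(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t100\nchr1\t10\t46\nchr1\tx\t20\n")
        rs = load_reads(p)
        assert rs.total_mapped_reads == 1
        assert rs.n_skipped == 2


class TestScaleFactors:
    def test_definition(self):
        assert library_scale_factors({"A": 1_000_000, "B": 2_000_000}) == {"A": 1.0, "B": 0.5}
        assert library_scale_factors({"A": 7}) == {"A": 1.0}
        assert library_scale_factors({"A": 3, "B": 5, "C": 7}) == {"A": 1.0, "B": 0.6, "C": 3 / 7}

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            library_scale_factors({"A": 0, "B": 5})


class TestAssignReads:
    def _one_gene(self):
        t = TranscriptModel("G", "T", "chr1", "+", 10_000, 15_000)
        return {"G": derive_windows(t)}, {"G": t.span}

    def test_read_in_tss_window_counted(self):
        windows, spans = self._one_gene()
        res = assign_reads([ReadRecord("chr1", 10_000, 10_036)], windows, spans)
        counts = res.counts.set_index("window_kind")["raw_count"]
        assert counts["tss"] == 1 and counts["body"] == 0
        assert res.n_assigned == 1 and res.n_discarded_multi_gene == 0

    def test_read_spanning_two_genes_discarded(self):
        t1 = TranscriptModel("G1", "T1", "chr1", "+", 1_000, 5_000)
        t2 = TranscriptModel("G2", "T2", "chr1", "+", 5_100, 9_000)
        windows = {g: derive_windows(t) for g, t in (("G1", t1), ("G2", t2))}
        spans = {"G1": t1.span, "G2": t2.span}
        res = assign_reads([ReadRecord("chr1", 4_990, 5_150)], windows, spans)
        assert res.n_discarded_multi_gene == 1
        assert res.counts["raw_count"].sum() == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_oracle_equivalence_on_random_fixtures(self, seed):
        """Indexed counting equals the all-pairs brute-force scan."""
        rng = np.random.default_rng(seed)
        transcripts, spans, windows = random_gene_fixture(rng)
        reads = random_reads(rng, n_reads=1000)
        res = assign_reads(reads, windows, spans)
        oracle, oracle_discarded = brute_force_assign(reads, windows, spans)
        got = res.counts.set_index(["transcript_id", "window_kind"])["raw_count"].to_dict()
        for key, expected in oracle.items():
            assert got.get(key, 0) == expected, key
        assert res.n_discarded_multi_gene == oracle_discarded

    @pytest.mark.parametrize("seed", [3, 17])
    def test_conservation_of_reads(self, seed):
        rng = np.random.default_rng(seed)
        transcripts, spans, windows = random_gene_fixture(rng)
        reads = random_reads(rng, n_reads=800)
        res = assign_reads(reads, windows, spans)
        assert res.n_assigned + res.n_discarded_multi_gene + res.n_outside == len(reads)


class TestDensity:
    def test_density_definition_and_linearity(self):
        import pandas as pd

        counts = pd.DataFrame(
            {
                "gene_id": ["G", "G"],
                "transcript_id": ["T", "T"],
                "window_kind": ["tss", "body"],
                "raw_count": [200, 0],
                "window_length": [2_000, 1_000],
            }
        )
        full = coverage.window_density(counts, scale_factor=1.0)
        half = coverage.window_density(counts, scale_factor=0.5)
        assert full["density"].tolist() == [0.1, 0.0]
        assert np.allclose(half["density"], full["density"] * 0.5)

    def test_zero_length_window_flagged_nan(self):
        import pandas as pd

        counts = pd.DataFrame(
            {
                "gene_id": ["G"],
                "transcript_id": ["T"],
                "window_kind": ["body"],
                "raw_count": [0],
                "window_length": [0],
            }
        )
        out = coverage.window_density(counts)
        assert np.isnan(out["density"].iloc[0])


class TestMeanBodyDepth:
    def test_single_read(self):
        body = GenomicInterval("chr1", 1_000, 2_000)
        assert coverage.mean_body_depth([ReadRecord("chr1", 1_200, 1_300)], body) == 0.1
        assert coverage.mean_body_depth([], body) == 0.0

    @pytest.mark.parametrize("seed", [0, 9])
    def test_matches_pileup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        body = GenomicInterval("chrT", 50_000, 53_000)
        reads = random_reads(rng, n_reads=500, genome=60_000)
        got = coverage.mean_body_depth(reads, body, scale_factor=0.7)
        assert got == pytest.approx(0.7 * pileup_mean_depth(reads, body))


class TestBinnedProfile:
    def test_flat_and_spike(self):
        flank = GenomicInterval("chr1", 10_000, 14_500)
        flat = [ReadRecord("chr1", 10_000 + i * 50 + 5, 10_000 + i * 50 + 41) for i in range(90)]
        row = coverage.binned_profile(flat, flank, "+", bin_size=50)
        assert np.all(row == 1.0)
        # all reads at the TSS: single spike at bin 2000/bin_size
        tss = 12_000
        spike = [ReadRecord("chr1", tss - 17, tss + 18)] * 10  # midpoint at the TSS
        row = coverage.binned_profile(spike, flank, "+", bin_size=50)
        assert row[2_000 // 50] == 10 and row.sum() == 10

    def test_minus_strand_row_is_mirror_of_plus(self):
        """Mirror oracle: reflected fixture on '-' equals the '+' row."""
        rng = np.random.default_rng(4)
        pivot = 1_000_000
        flank = GenomicInterval("chr1", 40_000, 44_500)
        reads = []
        for _ in range(300):
            start = int(rng.integers(39_000, 45_000))
            reads.append(ReadRecord("chr1", start, start + 35))  # odd length: exact mirror
        mirrored = [
            ReadRecord("chr1", pivot - r.end + 1, pivot - r.start + 1) for r in reads
        ]
        mirrored_flank = GenomicInterval("chr1", pivot - flank.end + 1, pivot - flank.start + 1)
        plus_row = coverage.binned_profile(reads, flank, "+", bin_size=50)
        minus_row = coverage.binned_profile(mirrored, mirrored_flank, "-", bin_size=50)
        assert np.array_equal(plus_row, minus_row)


def test_bedgraph_is_half_open_and_scaled():
    reads = [ReadRecord("chr1", 10, 46), ReadRecord("chr1", 12, 48)]
    text = coverage.coverage_bedgraph(reads, bin_size=50, scale_factor=0.5)
    assert text == "chr1\t0\t50\t1\n"
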