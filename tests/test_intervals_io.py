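import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mutspot import (
    GenomeIndex,
    GenomicInterval,
    ScoreTrack,
    build_flank,
    make_windows,
    read_bed,
    read_bedgraph,
    read_chrom_sizes,
    read_fasta,
    write_bed,
    write_chrom_sizes,
    write_fasta,
)


class TestGenomicInterval:
    def test_length_is_half_open(self):
        assert GenomicInterval("chr12", 25398250, 25398300).length == 50

    @pytest.mark.parametrize("start,end", [(5, 5), (10, 5), (-1, 5)])
    def test_rejects_degenerate(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("c1", start, end)

    def test_overlap_and_containment(self):
        a = GenomicInterval("c1", 10, 20)
        assert a.contains(10) and not a.contains(20)
        assert a.overlaps(GenomicInterval("c1", 19, 30))
        assert not a.overlaps(GenomicInterval("c1", 20, 30))
        assert not a.overlaps(GenomicInterval("c2", 10, 20))


class TestMakeWindows:
    def test_trailing_subwidth_window_kept(self):
        wins = make_windows(GenomeIndex({"c1": 125}), 50)
        assert [(w.start, w.end) for w in wins] == [(0, 50), (50, 100), (100, 125)]

    def test_exact_tiling(self):
        wins = make_windows(GenomeIndex({"c1": 100}), 50)
        assert len(wins) == 2 and all(w.length == 50 for w in wins)

    def test_empty_genome_errors(self):
        with pytest.raises(ValueError, match="no chromosomes"):
            make_windows(GenomeIndex({}), 50)

    @settings(deadline=None, max_examples=50)
    @given(
        lengths=st.lists(st.integers(1, 500), min_size=1, max_size=4),
        width=st.integers(1, 120),
    )
    def test_tiling_property(self, lengths, width):
        """Windows cover the genome without gaps or overlaps."""
        genome = GenomeIndex({f"c{i}": n for i, n in enumerate(lengths)})
        wins = make_windows(genome, width)
        assert sum(w.length for w in wins) == genome.total_length
        by_chrom = {}
        for w in wins:
            by_chrom.setdefault(w.chrom, []).append(w)
        for chrom, ws in by_chrom.items():
            assert ws[0].start == 0
            assert ws[-1].end == genome.chrom_lengths[chrom]
            for a, b in zip(ws, ws[1:]):
                assert a.end == b.start


class TestBuildFlank:
    def test_truncation_at_chromosome_start(self):
        genome = GenomeIndex({"c1": 10**6})
        flank = build_flank(GenomicInterval("c1", 0, 50), genome, 500_000)
        assert flank.left is None
        assert (flank.right.start, flank.right.end) == (50, 500_050)

    def test_truncation_at_both_ends(self):
        genome = GenomeIndex({"c1": 2000})
        flank = build_flank(GenomicInterval("c1", 1000, 1050), genome, 500_000)
        assert (flank.left.start, flank.left.end) == (0, 1000)
        assert (flank.right.start, flank.right.end) == (1050, 2000)

    def test_interior_symmetry_uniform_mappability(self):
        genome = GenomeIndex({"c1": 2 * 10**6})
        track = ScoreTrack.constant(genome, 1.0)
        flank = build_flank(
            GenomicInterval("c1", 600_000, 600_050), genome, 500_000, track, 0.5
        )
        assert flank.n_valid_left == flank.n_valid_right == 500_000

    def test_window_itself_excluded(self):
        genome = GenomeIndex({"c1": 10_000})
        flank = build_flank(GenomicInterval("c1", 5000, 5050), genome, 1000)
        assert flank.left.end == 5000 and flank.right.start == 5050

    def test_window_outside_genome_errors(self):
        with pytest.raises(ValueError):
            build_flank(GenomicInterval("c1", 90, 200), GenomeIndex({"c1": 100}), 10)

    def test_mask_monotone_in_threshold(self, rng):
        genome = GenomeIndex({"c1": 5000})
        track = ScoreTrack({"c1": rng.random(5000)})
        window = GenomicInterval("c1", 2000, 2050)
        totals = [
            build_flank(window, genome, 1000, track, thr).n_valid_left
            + build_flank(window, genome, 1000, track, thr).n_valid_right
            for thr in (0.9, 0.5, 0.1)
        ]
        assert totals == sorted(totals)

    def test_missing_mappability_is_invalid(self):
        genome = GenomeIndex({"c1": 300})
        arr = np.ones(300)
        arr[100:120] = np.nan
        flank = build_flank(
            GenomicInterval("c1", 140, 160), genome, 100, ScoreTrack({"c1": arr}), 0.5
        )
        assert flank.n_valid_left == 100 - 20


class TestScoreTrack:
    def test_point_query_and_missing(self):
        arr = np.array([1.0, np.nan, 3.0])
        track = ScoreTrack({"c1": arr})
        assert track.at("c1", 0) == 1.0
        assert np.isnan(track.at("c1", 1))

    def test_out_of_bounds_is_error_not_default(self):
        track = ScoreTrack({"c1": np.zeros(10)})
        with pytest.raises(IndexError):
            track.at("c1", 10)
        with pytest.raises(KeyError):
            track.at("c9", 0)
        with pytest.raises(IndexError):
            track.values_at("c1", np.array([3, 11]))


class TestFileFormats:
    def test_bed_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t60\n")
        assert read_bed(p) == [GenomicInterval("chr1", 10, 60)]

    def test_bed_extra_columns_tolerated(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t60\tname\t0\t+\n")
        assert read_bed(p) == [GenomicInterval("chr1", 10, 60)]

    def test_bed_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t60\nchr1\t5\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed(p)

    def test_bed_round_trip_random_intervals(self, tmp_path, rng):
        ivs = []
        for _ in range(1000):
            start = int(rng.integers(0, 10**6))
            ivs.append(
                GenomicInterval(
                    f"chr{rng.integers(1, 5)}", start, start + int(rng.integers(1, 500))
                )
            )
        path = tmp_path / "rt.bed"
        write_bed(ivs, path)
        assert read_bed(path) == ivs

    def test_bedgraph_expands_per_base(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t3\t1.5\n")
        track = read_bedgraph(p)
        assert [track.at("chr1", i) for i in range(3)] == [1.5, 1.5, 1.5]

    def test_bedgraph_overlap_is_ambiguous(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t0\t5\t1.0\nchr1\t4\t8\t2.0\n")
        with pytest.raises(ValueError, match="ambiguous track value"):
            read_bedgraph(p)

    def test_bedgraph_uncovered_positions_missing(self, tmp_path):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t2\t4\t7.0\n")
        genome = GenomeIndex({"chr1": 6})
        track = read_bedgraph(p, genome)
        assert np.isnan(track.at("chr1", 0)) and track.at("chr1", 3) == 7.0

    def test_chrom_sizes_round_trip(self, tmp_path):
        genome = GenomeIndex({"chr1": 1000, "chr2": 500})
        path = tmp_path / "g.sizes"
        write_chrom_sizes(genome, path)
        assert read_chrom_sizes(path).chrom_lengths == genome.chrom_lengths

    def test_fasta_normalizes_alphabet(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nacgtRYacgt\n")
        genome = read_fasta(p)
        assert genome.sequence("c1", 0, 10) == "ACGTNNACGT"

    def test_fasta_round_trip(self, tmp_path, tiny_genome):
        path = tmp_path / "g.fa"
        write_fasta(tiny_genome, path)
        back = read_fasta(path)
        assert back.sequences == tiny_genome.sequences
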