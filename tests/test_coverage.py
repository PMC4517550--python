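"""Alignment filtering, per-base depth, region summaries and bedGraph I/O."""

import numpy as np
import pysam
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fusionbleed as fb
from fusionbleed.annotation import partition_unique_shared
from fusionbleed.coverage import (
    AlignmentFilter,
    BedGraphFormatError,
    DepthTrack,
    collapse_mates,
    region_summary,
)
from fusionbleed.intervals import GenomicInterval

from conftest import per_base_depth_oracle


def _rec(header, name="r", start=10, mapq=30, flag=0x1 | 0x2 | 0x40 | 0x20,
         tlen=100, mate_start=35, cigar=((0, 50),)):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_id = 0
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigartuples = list(cigar)
    a.flag = flag
    a.next_reference_id = 0
    a.next_reference_start = mate_start
    a.template_length = tlen
    return a


@pytest.fixture()
def header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chrT", "LN": 10_000}]}
    )


class TestFilterAlignments:
    def test_mapq_below_threshold_removed(self, header):
        recs = [_rec(header, mapq=9), _rec(header, mapq=10)]
        kept = fb.filter_alignments(recs, AlignmentFilter(min_mapq=10))
        assert [r.mapping_quality for r in kept] == [10]

    def test_empty_input(self):
        assert fb.filter_alignments([]) == []

    def test_hand_written_orientation_cases(self, header):
        F, R, M1, M2, P = 0x0, 0x10, 0x40, 0x80, 0x1 | 0x2
        mrev = 0x20
        recs = [
            # 1-2: proper inward pair (forward leftmost)
            _rec(header, "a", start=10, flag=P | M1 | mrev, tlen=100, mate_start=60),
            _rec(header, "a", start=60, flag=P | M2 | R, tlen=-100, mate_start=10),
            # 3: same-strand pair -> fails orientation
            _rec(header, "b", start=10, flag=P | M1, tlen=100, mate_start=60),
            # 4: outward-facing (reverse read leftmost) -> fails
            _rec(header, "c", start=10, flag=P | M1 | R | mrev, tlen=100, mate_start=60),
            # 5-6: another proper pair
            _rec(header, "d", start=200, flag=P | M1 | mrev, tlen=80, mate_start=230),
            _rec(header, "d", start=230, flag=P | M2 | R, tlen=-80, mate_start=200),
        ]
        kept = fb.filter_alignments(recs, AlignmentFilter(min_mapq=0))
        assert [r.query_name for r in kept] == ["a", "a", "d", "d"]

    def test_insert_size_filter(self, header):
        recs = [_rec(header, tlen=600_000), _rec(header, tlen=-400)]
        kept = fb.filter_alignments(recs, AlignmentFilter(max_insert=500_000))
        assert len(kept) == 1 and kept[0].template_length == -400

    def test_order_preserved_and_bad_record_rejected(self, header):
        recs = [_rec(header, name=f"r{i}", mapq=30) for i in range(5)]
        assert [r.query_name for r in fb.filter_alignments(recs)] == [f"r{i}" for i in range(5)]
        with pytest.raises(TypeError):
            fb.filter_alignments(["not a record"])


class TestComputeDepth:
    def test_no_records_zero_track(self):
        w = GenomicInterval("chrT", 0, 50)
        track = fb.compute_depth([], w)
        assert track.depth.sum() == 0 and len(track.depth) == 50

    def test_toy_records_match_brute_force(self, header):
        w = GenomicInterval("chrT", 0, 50)
        recs = [
            _rec(header, start=0, cigar=((0, 20),)),
            _rec(header, start=10, cigar=((0, 10), (3, 5), (0, 10))),  # skip block
            _rec(header, start=30, cigar=((0, 30),)),  # extends past window
            _rec(header, start=5, cigar=((0, 40),)),
            _rec(header, start=48, cigar=((0, 2),)),
        ]
        track = fb.compute_depth(recs, w)
        assert np.array_equal(track.depth, per_base_depth_oracle(recs, w))
        # intron-skip bases contribute nothing
        assert track.depth[21] == per_base_depth_oracle(recs, w)[21]

    def test_simulated_records_match_brute_force(self, default_locus, sim_small):
        records, _ = sim_small
        sub = records[:100]
        track = fb.compute_depth(sub, default_locus.window)
        assert np.array_equal(track.depth, per_base_depth_oracle(sub, default_locus.window))

    def test_cap_clipping_and_monotonicity(self, header):
        w = GenomicInterval("chrT", 0, 30)
        recs = [_rec(header, start=5, cigar=((0, 10),)) for _ in range(10)]
        capped = fb.compute_depth(recs, w, cap=3)
        uncapped = fb.compute_depth(recs, w)
        assert capped.depth.max() == 3
        assert (capped.depth <= uncapped.depth).all()
        assert np.array_equal(
            capped.depth[uncapped.depth <= 3], uncapped.depth[uncapped.depth <= 3]
        )

    def test_sum_conservation(self, default_locus, sim_small):
        records, _ = sim_small
        track = fb.compute_depth(records, default_locus.window)
        w = default_locus.window
        expected = sum(
            max(0, min(be, w.end) - max(bs, w.start))
            for r in records
            for bs, be in r.get_blocks()
        )
        assert int(track.depth.sum()) == expected

    def test_collapse_mates_halves_pairs(self, sim_small):
        records, truth = sim_small
        assert len(collapse_mates(records)) == len(truth)


class TestRegionSummary:
    def test_uniform_depth(self, default_locus, locus_ann, fusion_tid):
        w = default_locus.window
        track = DepthTrack(window=w, depth=np.full(w.length, 7))
        part = partition_unique_shared(locus_ann.transcript(fusion_tid), locus_ann)
        summary = region_summary(track, part)
        assert (summary["mean_depth"] == 7).all()

    def test_hand_computed_two_segments(self, locus_ann, ins_tid):
        w = GenomicInterval("chr11", 2_179_000, 2_182_000)
        depth = np.zeros(w.length, dtype=int)
        depth[2_180_000 - w.start : 2_180_400 - w.start] = 4  # exon B
        depth[2_181_000 - w.start : 2_181_300 - w.start] = 10  # half of exon A
        track = DepthTrack(window=w, depth=depth)
        part = partition_unique_shared(locus_ann.transcript(ins_tid), locus_ann)
        summary = region_summary(track, part).set_index("segment")
        assert summary.loc["chr11:2180000-2180400", "mean_depth"] == 4.0
        assert summary.loc["chr11:2181000-2181600", "mean_depth"] == pytest.approx(5.0)
        assert summary.loc["chr11:2181000-2181600", "summed_depth"] == 3000
        # per-status aggregates conserve the summed depth
        seg_rows = summary[~summary.index.str.startswith("all_")]
        for status in ("unique", "shared"):
            assert (
                summary.loc[f"all_{status}", "summed_depth"]
                == seg_rows[seg_rows["status"] == status]["summed_depth"].sum()
            )

    def test_segment_outside_window_raises(self, locus_ann, ins_tid):
        w = GenomicInterval("chr11", 2_180_500, 2_182_000)
        track = DepthTrack(window=w, depth=np.zeros(w.length, dtype=int))
        part = partition_unique_shared(locus_ann.transcript(ins_tid), locus_ann)
        with pytest.raises(ValueError, match="outside"):
            region_summary(track, part)

    def test_shared_vs_fusion_unique_depth_pattern(self, default_locus, locus_ann, fusion_tid):
        """The qualitative signature: shared-exon depth dwarfs fusion-unique depth,
        while the short gene's two exons sit at the same order of magnitude."""
        records, _ = fb.simulate_reads(default_locus, 20_000, seed=13)
        filtered = fb.filter_alignments(records)
        track = fb.compute_depth(filtered, default_locus.window)
        part = partition_unique_shared(locus_ann.transcript(fusion_tid), locus_ann)
        summary = region_summary(track, part).set_index("segment")
        shared_mean = summary.loc["all_shared", "mean_depth"]
        unique_mean = summary.loc["all_unique", "mean_depth"]
        assert shared_mean > 100 * max(unique_mean, 1e-12)
        ins_part = partition_unique_shared(locus_ann.transcript("INS-like-001"), locus_ann)
        ins_sum = region_summary(track, ins_part).set_index("segment")
        exon_a = ins_sum.loc["chr11:2181000-2181600", "mean_depth"]
        exon_b = ins_sum.loc["chr11:2180000-2180400", "mean_depth"]
        assert 0.1 < exon_a / exon_b < 10  # same order of magnitude


class TestBedGraph:
    def test_small_track_round_trip(self, tmp_path):
        w = GenomicInterval("chrT", 100, 106)
        track = DepthTrack(window=w, depth=np.array([0, 0, 5, 5, 5, 0]))
        path = tmp_path / "t.bedgraph"
        fb.write_bedgraph(track, path)
        data_lines = [
            l for l in path.read_text().splitlines() if l and not l.startswith("#")
        ]
        assert len(data_lines) == 1  # one nonzero run
        assert fb.read_bedgraph(path) == track

    def test_all_zero_track(self, tmp_path):
        w = GenomicInterval("chrT", 0, 10)
        track = DepthTrack(window=w, depth=np.zeros(10, dtype=int))
        path = tmp_path / "z.bedgraph"
        fb.write_bedgraph(track, path)
        assert not [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert fb.read_bedgraph(path) == track

    @given(st.lists(st.integers(0, 20), min_size=1, max_size=60))
    def test_random_track_round_trip(self, values):
        import tempfile, os

        w = GenomicInterval("chrT", 50, 50 + len(values))
        track = DepthTrack(window=w, depth=np.array(values))
        fd, path = tempfile.mkstemp(suffix=".bedgraph")
        os.close(fd)
        try:
            fb.write_bedgraph(track, path)
            assert fb.read_bedgraph(path) == track
        finally:
            os.unlink(path)

    def test_overlapping_intervals_rejected(self, tmp_path):
        path = tmp_path / "bad.bedgraph"
        path.write_text("# window=chrT:1-100\nchrT\t0\t10\t3\nchrT\t5\t15\t2\n")
        with pytest.raises(BedGraphFormatError, match="overlap"):
            fb.read_bedgraph(path)
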