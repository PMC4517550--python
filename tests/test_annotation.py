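"""Gene-model parsing, unique/shared partitioning and the exon-sharing census."""

import numpy as np
import pytest

import fusionbleed as fb
from fusionbleed.annotation import (
    Annotation,
    GtfParseError,
    TranscriptModel,
    UnknownTranscriptError,
    exonic_union,
    partition_unique_shared,
)
from fusionbleed.intervals import GenomicInterval


def iv(s, e, strand="+", chrom="chr1"):
    return GenomicInterval(chrom, s, e, strand)


def tm(tid, gid, exons, strand="+", biotype="protein_coding"):
    return TranscriptModel(tid, gid, biotype, tuple(exons), strand)


# ---------------------------------------------------------------------------
# GTF reading


class TestReadGtf:
    def test_toy_gtf_manual_parse(self, toy_gtf):
        ann = fb.read_gtf(toy_gtf)
        assert sorted(ann.genes) == ["gA", "gB"]
        assert [t.transcript_id for t in ann.transcripts] == ["tA1", "tA2", "tB1"]
        # 1-based inclusive 101..200 becomes 0-based half-open [100, 200)
        ta1 = ann.transcript("tA1")
        assert [(e.start, e.end) for e in ta1.exons] == [(100, 200), (300, 400)]
        assert ann.transcript("tB1").exons[0].start == 150

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.gtf"
        p.write_text("")
        assert fb.read_gtf(p).genes == {}

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text("chr1\ttoy\texon\t101\n")
        with pytest.raises(GtfParseError, match="line 1"):
            fb.read_gtf(p)

    def test_exon_without_transcript_id(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\ttoy\texon\t101\t200\t.\t+\t.\tgene_id "gA";\n')
        with pytest.raises(GtfParseError, match="transcript_id"):
            fb.read_gtf(p)

    def test_gtf_write_read_round_trip(self, default_locus, tmp_path):
        ann = default_locus.annotation()
        path = tmp_path / "locus.gtf"
        fb.write_gtf(ann, path)
        back = fb.read_gtf(path)
        for t in ann.transcripts:
            t2 = back.transcript(t.transcript_id)
            assert t2.exons == t.exons and t2.gene_id == t.gene_id


# ---------------------------------------------------------------------------
# Exonic union


@pytest.mark.parametrize(
    "exons, expected",
    [
        ([(100, 200), (300, 400)], [(100, 200), (300, 400)]),
        ([(100, 200)], [(100, 200)]),
    ],
)
def test_exonic_union_of_valid_model(exons, expected):
    t = tm("t", "g", [iv(s, e) for s, e in exons])
    assert [(u.start, u.end) for u in exonic_union(t)] == expected


def test_exonic_union_merges_raw_overlapping_intervals():
    # relaxed input: raw intervals, verified against per-base membership
    raw = [iv(100, 200), iv(150, 250)]
    got = exonic_union(raw)
    assert [(u.start, u.end) for u in got] == [(100, 250)]
    member = {p for r in raw for p in range(r.start, r.end)}
    assert {p for u in got for p in range(u.start, u.end)} == member


# ---------------------------------------------------------------------------
# Unique/shared partitioning


def partition_oracle(t, ann, cross_gene_only=True, same_strand=True):
    """O(bases x exons) per-base membership oracle."""
    status = {}
    for uiv in exonic_union(t):
        for p in range(uiv.start, uiv.end):
            sharers = set()
            for other in ann.transcripts:
                if other.transcript_id == t.transcript_id:
                    continue
                if cross_gene_only and other.gene_id == t.gene_id:
                    continue
                if same_strand and other.strand != t.strand:
                    continue
                if other.chrom == t.chrom and any(e.start <= p < e.end for e in other.exons):
                    sharers.add(other.transcript_id)
            status[p] = frozenset(sharers)
    return status


def assert_partition_matches_oracle(t, ann, **kw):
    part = partition_unique_shared(t, ann, **kw)
    oracle = partition_oracle(t, ann, **kw)
    seen = {}
    for seg in part.segments:
        for p in range(seg.interval.start, seg.interval.end):
            assert p not in seen, "segments overlap"
            seen[p] = seg.sharer_ids
            assert (seg.status == "shared") == bool(seg.sharer_ids)
    assert seen == oracle


class TestPartition:
    def test_default_locus_ins_like(self, default_locus, locus_ann, ins_tid, fusion_tid):
        part = partition_unique_shared(locus_ann.transcript(ins_tid), locus_ann)
        by_status = {
            seg.status: (seg.interval.start, seg.interval.end) for seg in part.segments
        }
        assert by_status["shared"] == (2_181_000, 2_181_600)  # exon A
        assert by_status["unique"] == (2_180_000, 2_180_400)  # exon B
        shared_seg = next(s for s in part.segments if s.status == "shared")
        assert shared_seg.sharer_ids == {fusion_tid}
        assert_partition_matches_oracle(locus_ann.transcript(ins_tid), locus_ann)

    def test_default_locus_fusion(self, locus_ann, fusion_tid):
        t = locus_ann.transcript(fusion_tid)
        part = partition_unique_shared(t, locus_ann)
        assert [s.status for s in part.segments] == ["unique", "unique", "shared"]
        assert part.unique_length == 1500 and part.shared_length == 600
        assert_partition_matches_oracle(t, locus_ann)

    def test_single_gene_annotation_all_unique(self):
        t = tm("t1", "g1", [iv(0, 100), iv(200, 300)])
        ann = Annotation.from_transcripts([t])
        part = partition_unique_shared(t, ann, cross_gene_only=True)
        assert all(s.status == "unique" for s in part.segments)
        assert part.unique_length == t.spliced_length

    def test_partition_conservation_random_annotations(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            transcripts = []
            for g in range(3):
                for k in range(rng.integers(1, 3)):
                    n_ex = int(rng.integers(1, 4))
                    pos = np.sort(rng.choice(np.arange(0, 500, 10), 2 * n_ex, replace=False))
                    exons = [iv(int(pos[2 * i]), int(pos[2 * i + 1])) for i in range(n_ex)]
                    exons = [e for e in exons if e.length > 0]
                    if exons:
                        transcripts.append(tm(f"t{g}_{k}_{len(transcripts)}", f"g{g}", exons))
            if not transcripts:
                continue
            ann = Annotation.from_transcripts(transcripts)
            for t in transcripts:
                part = partition_unique_shared(t, ann)
                assert part.unique_length + part.shared_length == sum(
                    u.length for u in exonic_union(t)
                )
                assert_partition_matches_oracle(t, ann)

    def test_absent_transcript_raises(self, locus_ann):
        stray = tm("ghost", "g", [iv(0, 10, "-", chrom="chr11")], strand="-")
        with pytest.raises(UnknownTranscriptError):
            partition_unique_shared(stray, locus_ann)


# ---------------------------------------------------------------------------
# Interval index


def test_index_matches_linear_scan(locus_ann, default_locus):
    rng = np.random.default_rng(0)
    all_exons = [
        (ex, t.transcript_id) for t in locus_ann.transcripts for ex in t.exons
    ]
    w = default_locus.window
    for _ in range(1000):
        s = int(rng.integers(w.start, w.end - 1))
        e = int(rng.integers(s + 1, min(s + 5000, w.end) + 1))
        q = GenomicInterval(w.chrom, s, e)
        got = {(ex.start, ex.end, tid) for ex, tid, _gid in locus_ann.query_exons(q)}
        expected = {
            (ex.start, ex.end, tid) for ex, tid in all_exons if ex.overlaps(q)
        }
        assert got == expected


# ---------------------------------------------------------------------------
# Exon-sharing census


def census_oracle(ann, biotype="protein_coding", same_strand=True):
    """Exhaustive pairwise exon-intersection oracle."""
    partners = {}
    ts = [t for t in ann.transcripts if biotype is None or t.biotype == biotype]
    for a in ts:
        for b in ts:
            if a.transcript_id == b.transcript_id or a.gene_id == b.gene_id:
                continue
            if same_strand and a.strand != b.strand:
                continue
            if any(ea.intersection_length(eb) > 0 for ea in a.exons for eb in b.exons):
                partners.setdefault(a.transcript_id, set()).add(b.transcript_id)
    return {tid: sorted(p) for tid, p in partners.items()}


class TestCensus:
    def test_default_locus(self, locus_ann, ins_tid, fusion_tid, igf2_tid):
        census = dict(fb.find_exon_sharing_transcripts(locus_ann))
        assert census == {ins_tid: [fusion_tid], fusion_tid: [ins_tid]}
        assert igf2_tid not in census
        assert census == census_oracle(locus_ann)

    def test_non_overlapping_genes_empty(self):
        ann = Annotation.from_transcripts(
            [tm("t1", "g1", [iv(0, 100)]), tm("t2", "g2", [iv(200, 300)])]
        )
        assert fb.find_exon_sharing_transcripts(ann) == []

    def test_intron_only_overlap_empty(self):
        # gene 2's single exon sits wholly inside gene 1's intron
        ann = Annotation.from_transcripts(
            [
                tm("t1", "g1", [iv(0, 100), iv(500, 600)]),
                tm("t2", "g2", [iv(200, 300)]),
            ]
        )
        assert fb.find_exon_sharing_transcripts(ann) == []
        assert census_oracle(ann) == {}

    def test_symmetry_and_strand_option(self):
        ann = Annotation.from_transcripts(
            [
                tm("tp", "g1", [iv(0, 100, "+")], strand="+"),
                tm("tn", "g2", [iv(50, 150, "-")], strand="-"),
            ]
        )
        assert fb.find_exon_sharing_transcripts(ann) == []  # opposite strands
        both = dict(fb.find_exon_sharing_transcripts(ann, same_strand=False))
        assert both == {"tn": ["tp"], "tp": ["tn"]}

    def test_boundary_identity_mode(self):
        ann = Annotation.from_transcripts(
            [
                tm("t1", "g1", [iv(0, 100)]),
                tm("t2", "g2", [iv(50, 150)]),
                tm("t3", "g3", [iv(0, 100)]),
            ]
        )
        strict = dict(fb.find_exon_sharing_transcripts(ann, boundary_identity=True))
        assert strict == {"t1": ["t3"], "t3": ["t1"]}


# ---------------------------------------------------------------------------
# Contributing-transcripts report


def test_contributing_report_default_locus(locus_ann, ins_tid, fusion_tid):
    report = fb.contributing_transcripts_report(locus_ann).set_index("transcript_id")
    assert report.loc[ins_tid, "contributors"] == f"{fusion_tid}=600"
    assert report.loc[fusion_tid, "contributors"] == f"{ins_tid}=600"  # symmetric
    assert report.loc["IGF2-like-001", "contributors"] == ""
    # shared-base count equals the shared exon's length
    assert report.loc[ins_tid, "total_shared_bases"] == 600


def test_contributing_report_single_gene():
    ann = Annotation.from_transcripts(
        [tm("t1", "g1", [iv(0, 100)]), tm("t2", "g1", [iv(0, 100)])]
    )
    report = fb.contributing_transcripts_report(ann)
    assert (report["contributors"] == "").all()
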