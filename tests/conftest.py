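import numpy as np
import pysam
import pytest
from hypothesis import HealthCheck, settings

import fusionbleed as fb
from fusionbleed.locus import FUSION_TID, IGF2_TID, INS_TID

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def default_locus():
    return fb.build_default_locus(seed=1)


@pytest.fixture(scope="session")
def locus_ann(default_locus):
    return default_locus.annotation()


@pytest.fixture(scope="session")
def sim_small(default_locus):
    """A modest simulated dataset shared across read-level tests."""
    records, truth = fb.simulate_reads(default_locus, 5000, seed=7)
    return records, truth


@pytest.fixture()
def toy_gtf(tmp_path):
    """5 exon lines, 2 genes, 3 transcripts; 1-based inclusive coordinates."""
    lines = [
        'chr1\ttoy\texon\t101\t200\t.\t+\t.\tgene_id "gA"; transcript_id "tA1"; gene_biotype "protein_coding";',
        'chr1\ttoy\texon\t301\t400\t.\t+\t.\tgene_id "gA"; transcript_id "tA1"; gene_biotype "protein_coding";',
        'chr1\ttoy\texon\t101\t200\t.\t+\t.\tgene_id "gA"; transcript_id "tA2"; gene_biotype "protein_coding";',
        'chr1\ttoy\texon\t151\t250\t.\t+\t.\tgene_id "gB"; transcript_id "tB1"; gene_biotype "protein_coding";',
        'chr1\ttoy\texon\t501\t600\t.\t+\t.\tgene_id "gB"; transcript_id "tB1"; gene_biotype "protein_coding";',
    ]
    path = tmp_path / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path


def make_pair(spec, tid, spliced_start, frag_length, read_len=75, name="frag"):
    """Hand-construct one properly-paired fragment on a locus transcript."""
    from fusionbleed.locus import sam_header, _make_read

    t = spec.transcript(tid)
    header = sam_header(spec)
    s, L = spliced_start, frag_length
    frag_blocks = t.spliced_to_genomic(s, s + L)
    gstart, gend = frag_blocks[0].start, frag_blocks[-1].end
    b1 = t.spliced_to_genomic(s, s + read_len)
    b2 = t.spliced_to_genomic(s + L - read_len, s + L)
    r1 = _make_read(header, name, spec, t, s, s + read_len, True, gstart, gend, b2[0].start, True)
    r2 = _make_read(header, name, spec, t, s + L - read_len, s + L, False, gstart, gend, b1[0].start, True)
    return [r1, r2]


def make_unspliced_pair(spec, start, frag_length, read_len=75, name="frag", mapq=60):
    """A contiguous (non-transcript) pair, e.g. in intergenic sequence."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": spec.window.chrom, "LN": spec.window.end}]}
    )
    out = []
    for is_read1 in (True, False):
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.reference_id = 0
        a.reference_start = start if is_read1 else start + frag_length - read_len
        a.mapping_quality = mapq
        a.cigartuples = [(0, read_len)]
        a.flag = 0x1 | 0x2 | (0x40 if is_read1 else 0x80) | (0x20 if is_read1 else 0x10)
        a.next_reference_id = 0
        a.next_reference_start = start + frag_length - read_len if is_read1 else start
        a.template_length = frag_length if is_read1 else -frag_length
        out.append(a)
    return out


@pytest.fixture()
def ins_tid():
    return INS_TID


@pytest.fixture()
def fusion_tid():
    return FUSION_TID


@pytest.fixture()
def igf2_tid():
    return IGF2_TID


def per_base_depth_oracle(records, window):
    """Brute-force per-base membership count over aligned blocks."""
    depth = np.zeros(window.length, dtype=int)
    for rec in records:
        if rec.is_unmapped or rec.reference_name != window.chrom:
            continue
        for bs, be in rec.get_blocks():
            for p in range(max(bs, window.start), min(be, window.end)):
                depth[p - window.start] += 1
    return depth
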