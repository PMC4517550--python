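"""Synthetic test universe: an INS/INS-IGF2/IGF2-like locus with known truth.

The generator builds a 40 kb window containing three antisense-strand
transcripts that reproduce the topology responsible for the fusion-transcript
quantification artefact:

* a short, highly expressed two-exon gene (``INS-like``): exon A shared with
  the fusion transcript plus a unique exon B near the window end;
* a long, rare fusion transcript (``INS-IGF2-like``) owning exon A plus
  distal unique exons near the window middle, spliced length greater than
  the short gene's;
* a third gene (``IGF2-like``) near the window start overlapping nothing.

Default molar abundances put the short gene 20,000-fold above the fusion —
the regime in which multi-assignment quantification inflates the fusion's
apparent expression.  A seeded paired-end read simulator emits SAM-style
alignment records with a per-fragment truth table, and a Ct simulator
inverts the exponential-amplification model so the qPCR stage can be tested
against known abundance ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import reverse_complement
from scipy.stats import truncnorm

from .annotation import Annotation, TranscriptModel
from .intervals import GenomicInterval, format_region

log = logging.getLogger(__name__)

CHROM = "chr11"
WINDOW = GenomicInterval(CHROM, 2_150_000, 2_190_000, ".")

INS_TID = "INS-like-001"
FUSION_TID = "INS-IGF2-like-001"
IGF2_TID = "IGF2-like-001"

# Exon coordinates (0-based half-open, all antisense). Exon A is the first
# coding exon of the short gene in transcription order (highest coordinates
# on the minus strand) and is wholly shared with the fusion transcript.
_INS_EXON_B = (2_180_000, 2_180_400)   # unique to the short gene
_INS_EXON_A = (2_181_000, 2_181_600)   # shared with the fusion transcript
_FUSION_UNIQUE_MID = (2_170_000, 2_170_900)   # "2170000 area" unique exon
_FUSION_UNIQUE_DISTAL = (2_168_000, 2_168_600)
_IGF2_EXONS = ((2_152_000, 2_152_800), (2_154_000, 2_154_700), (2_156_000, 2_156_500))

DEFAULT_ABUNDANCES = {INS_TID: 20_000.0, FUSION_TID: 1.0, IGF2_TID: 4.0}

# Primer binding sites embedded in spliced (transcript-sense) coordinates:
# (transcript, forward-primer start, reverse-site start). Positions are
# chosen so set 1 spans the short gene's exon A/B junction into unique
# sequence, set 2 sits inside the fusion's middle unique exon and set 3
# inside the third gene's middle exon.
_PRIMER_SITES = {
    "Primerset1": (INS_TID, 520, 620),
    "Primerset2": (FUSION_TID, 900, 1000),
    "Primerset3": (IGF2_TID, 700, 800),
}


@dataclass
class LocusSpec:
    """A synthetic locus: window, sequence, transcripts and true abundances."""

    window: GenomicInterval
    sequence: str
    transcripts: list[TranscriptModel]
    abundances: dict[str, float]
    gene_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sequence) != self.window.length:
            raise ValueError("sequence length must equal window length")
        for t in self.transcripts:
            for ex in t.exons:
                if not (self.window.start <= ex.start and ex.end <= self.window.end):
                    raise ValueError(f"exon {ex} of {t.transcript_id} outside window")
        for tid, ab in self.abundances.items():
            if ab <= 0:
                raise ValueError(f"abundance of {tid} must be > 0, got {ab}")

    def annotation(self) -> Annotation:
        return Annotation.from_transcripts(self.transcripts, gene_names=self.gene_names)

    def transcript(self, tid: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == tid:
                return t
        raise KeyError(tid)

    def genomic_sequence(self, iv: GenomicInterval) -> str:
        return self.sequence[iv.start - self.window.start : iv.end - self.window.start]

    def transcript_sequence(self, tid: str) -> str:
        """Spliced mRNA-sense sequence of a transcript."""
        t = self.transcript(tid)
        genomic = "".join(self.genomic_sequence(ex) for ex in t.exons)
        return reverse_complement(genomic) if t.strand == "-" else genomic

    def transcript_sequences(self) -> dict[str, str]:
        return {t.transcript_id: self.transcript_sequence(t.transcript_id) for t in self.transcripts}


def _default_transcripts() -> list[TranscriptModel]:
    def iv(se: tuple[int, int]) -> GenomicInterval:
        return GenomicInterval(CHROM, se[0], se[1], "-")

    ins = TranscriptModel(
        transcript_id=INS_TID,
        gene_id="INS_like",
        biotype="protein_coding",
        exons=(iv(_INS_EXON_B), iv(_INS_EXON_A)),
        strand="-",
    )
    fusion = TranscriptModel(
        transcript_id=FUSION_TID,
        gene_id="INS_IGF2_like",
        biotype="protein_coding",
        exons=(iv(_FUSION_UNIQUE_DISTAL), iv(_FUSION_UNIQUE_MID), iv(_INS_EXON_A)),
        strand="-",
    )
    igf2 = TranscriptModel(
        transcript_id=IGF2_TID,
        gene_id="IGF2_like",
        biotype="protein_coding",
        exons=tuple(iv(se) for se in _IGF2_EXONS),
        strand="-",
    )
    return [ins, fusion, igf2]


def _embed_spliced(
    genome: bytearray, window: GenomicInterval, t: TranscriptModel, spliced_start: int, subseq: str
) -> None:
    """Write ``subseq`` (transcript sense) into the genome at a spliced position."""
    blocks = t.spliced_to_genomic(spliced_start, spliced_start + len(subseq))
    genomic_seq = reverse_complement(subseq) if t.strand == "-" else subseq
    offset = 0
    for b in blocks:
        piece = genomic_seq[offset : offset + b.length]
        genome[b.start - window.start : b.end - window.start] = piece.encode()
        offset += b.length


def build_default_locus(seed: int = 1) -> LocusSpec:
    """Build the default synthetic locus (deterministic per seed).

    Background sequence is random; the published primer binding sites are
    embedded at topologically corresponding positions (set 1 spanning the
    short gene's unique sequence, set 2 inside fusion-unique sequence,
    set 3 inside the third gene).  Default abundances are 20,000 : 1 for the
    short gene versus the fusion, with the third gene set independently.
    """
    from .primers import load_packaged_primer_sets  # local import: no cycle at module load

    rng = np.random.default_rng(seed)
    genome = bytearray(rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=WINDOW.length).tobytes())
    transcripts = _default_transcripts()
    by_tid = {t.transcript_id: t for t in transcripts}
    primer_sets = {p.name: p for p in load_packaged_primer_sets()}
    for name, (tid, fwd_pos, rev_pos) in _PRIMER_SITES.items():
        pair = primer_sets[name]
        t = by_tid[tid]
        _embed_spliced(genome, WINDOW, t, fwd_pos, pair.forward)
        _embed_spliced(genome, WINDOW, t, rev_pos, reverse_complement(pair.reverse))
    return LocusSpec(
        window=WINDOW,
        sequence=genome.decode(),
        transcripts=transcripts,
        abundances=dict(DEFAULT_ABUNDANCES),
        gene_names={"INS_like": "INS-like", "INS_IGF2_like": "INS-IGF2-like", "IGF2_like": "IGF2-like"},
    )


# ---------------------------------------------------------------------------
# Read simulation

TRUTH_TAG = "XT"  # SAM tag carrying the true transcript of origin


def sam_header(spec: LocusSpec, seed: int | None = None) -> pysam.AlignmentHeader:
    comments = [f"fusionbleed synthetic locus window={format_region(spec.window)}"]
    if seed is not None:
        comments.append(f"fusionbleed seed={seed}")
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": spec.window.chrom, "LN": spec.window.end}],
            "CO": comments,
        }
    )


def _truncated_normal_lengths(
    rng: np.random.Generator, n: int, mean: float, sd: float, low: int, high: int
) -> np.ndarray:
    """Integer fragment lengths from a normal truncated to [low, high]."""
    if high <= low:
        return np.full(n, low, dtype=int)
    if sd <= 0:
        return np.full(n, int(np.clip(round(mean), low, high)), dtype=int)
    a, b = (low - mean) / sd, (high - mean) / sd
    draws = truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.clip(np.rint(draws), low, high).astype(int)


def _make_read(
    header: pysam.AlignmentHeader,
    name: str,
    spec: LocusSpec,
    t: TranscriptModel,
    spliced_lo: int,
    spliced_hi: int,
    is_read1: bool,
    frag_gstart: int,
    frag_gend: int,
    mate_gstart: int,
    with_sequence: bool,
) -> pysam.AlignedSegment:
    blocks = t.spliced_to_genomic(spliced_lo, spliced_hi)
    # On the minus strand the transcript 5' read aligns to the reverse strand.
    reverse = (t.strand == "-") == is_read1
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_id = 0
    a.reference_start = blocks[0].start
    a.mapping_quality = 60
    cigar = []
    prev_end = None
    for b in blocks:
        if prev_end is not None and b.start > prev_end:
            cigar.append((3, b.start - prev_end))  # N: intron skip
        cigar.append((0, b.length))  # M
        prev_end = b.end
    a.cigartuples = cigar
    flag = 0x1 | 0x2  # paired, proper pair
    flag |= 0x40 if is_read1 else 0x80
    if reverse:
        flag |= 0x10
    else:
        flag |= 0x20  # mate is on the reverse strand
    a.flag = flag
    a.next_reference_id = 0
    a.next_reference_start = mate_gstart
    span = frag_gend - frag_gstart
    a.template_length = span if a.reference_start == frag_gstart else -span
    if with_sequence:
        # SEQ is stored genome-forward, as an aligner would record it.
        a.query_sequence = "".join(spec.genomic_sequence(b) for b in blocks)
    a.set_tag(TRUTH_TAG, t.transcript_id, value_type="Z")
    return a


def simulate_reads(
    spec: LocusSpec,
    n_fragments: int,
    frag_len_mean: float = 300.0,
    frag_len_sd: float = 30.0,
    read_len: int = 75,
    seed: int = 0,
    with_sequence: bool = True,
) -> tuple[list[pysam.AlignedSegment], pd.DataFrame]:
    """Simulate properly-paired spliced alignments with per-fragment truth.

    Fragments are drawn per transcript with probability proportional to
    abundance x effective spliced length (effective length = spliced length
    - mean fragment length + 1, floored at 1); the spliced start is uniform
    over valid positions and the fragment length is a truncated normal on
    [read_len, spliced length].  Each mate is projected to genomic
    coordinates, splitting across exon junctions into match blocks separated
    by intron skips.  Returns (records, truth table); the truth table has one
    row per fragment (fragment_id, transcript_id, spliced_start,
    frag_length) and each record carries the true transcript in the ``XT``
    tag.  Deterministic for a given seed.
    """
    if n_fragments <= 0:
        raise ValueError("n_fragments must be > 0")
    if read_len > frag_len_mean:
        raise ValueError("read_len must not exceed frag_len_mean")
    rng = np.random.default_rng(seed)
    usable: list[TranscriptModel] = []
    for t in spec.transcripts:
        if t.spliced_length < read_len:
            log.warning(
                "transcript %s (spliced length %d) shorter than read length %d; excluded",
                t.transcript_id,
                t.spliced_length,
                read_len,
            )
        else:
            usable.append(t)
    if not usable:
        raise ValueError("no transcript long enough to simulate from")
    lengths = np.array([t.spliced_length for t in usable], dtype=float)
    abund = np.array([spec.abundances[t.transcript_id] for t in usable], dtype=float)
    eff_len = np.maximum(lengths - frag_len_mean + 1.0, 1.0)
    weights = abund * eff_len
    probs = weights / weights.sum()
    tx_idx = rng.choice(len(usable), size=n_fragments, p=probs)

    frag_len = np.empty(n_fragments, dtype=int)
    for k, t in enumerate(usable):
        mask = tx_idx == k
        if mask.any():
            frag_len[mask] = _truncated_normal_lengths(
                rng, int(mask.sum()), frag_len_mean, frag_len_sd, read_len, t.spliced_length
            )
    max_start = np.array([usable[k].spliced_length for k in tx_idx]) - frag_len
    starts = rng.integers(0, max_start + 1)

    header = sam_header(spec, seed=seed)
    records: list[pysam.AlignedSegment] = []
    truth_rows = {
        "fragment_id": [],
        "transcript_id": [],
        "spliced_start": [],
        "frag_length": [],
    }
    for i in range(n_fragments):
        t = usable[tx_idx[i]]
        s, L = int(starts[i]), int(frag_len[i])
        name = f"frag{i:07d}"
        frag_blocks = t.spliced_to_genomic(s, s + L)
        frag_gstart, frag_gend = frag_blocks[0].start, frag_blocks[-1].end
        r1_lo, r1_hi = s, s + read_len
        r2_lo, r2_hi = s + L - read_len, s + L
        b1 = t.spliced_to_genomic(r1_lo, r1_hi)
        b2 = t.spliced_to_genomic(r2_lo, r2_hi)
        rec1 = _make_read(
            header, name, spec, t, r1_lo, r1_hi, True, frag_gstart, frag_gend, b2[0].start, with_sequence
        )
        rec2 = _make_read(
            header, name, spec, t, r2_lo, r2_hi, False, frag_gstart, frag_gend, b1[0].start, with_sequence
        )
        records.extend((rec1, rec2))
        truth_rows["fragment_id"].append(name)
        truth_rows["transcript_id"].append(t.transcript_id)
        truth_rows["spliced_start"].append(s)
        truth_rows["frag_length"].append(L)
    truth = pd.DataFrame(truth_rows)
    return records, truth


# ---------------------------------------------------------------------------
# Ct simulation


def simulate_ct(
    rel_abundance: dict[str, float],
    efficiency: float = 1.0,
    intercept_ct: float = 38.0,
    noise_sd: float = 0.0,
    max_cycles: float = 40.0,
    n_preps: int = 3,
    seed: int = 0,
    sample: str = "sim",
) -> pd.DataFrame:
    """Generate a Ct table from relative abundances.

    Ct = intercept_ct - log(abundance)/log(1 + efficiency) + N(0, noise_sd),
    drawn independently per technical replicate (two per preparation);
    values above ``max_cycles`` are recorded as missing (NaN, serialized as
    "NoCt").  ``efficiency`` is the per-cycle amplification gain in (0, 1];
    1.0 means perfect doubling so one cycle equals one log2 unit.
    """
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    for gene, ab in rel_abundance.items():
        if ab <= 0:
            raise ValueError(f"abundance of {gene} must be > 0, got {ab}")
    rng = np.random.default_rng(seed)
    denom = np.log(1.0 + efficiency)
    rows = []
    for gene, ab in rel_abundance.items():
        base = intercept_ct - np.log(ab) / denom
        for prep in range(1, n_preps + 1):
            for replicate in (1, 2):
                ct = base + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append(
                    {
                        "sample": sample,
                        "gene": gene,
                        "prep": prep,
                        "replicate": replicate,
                        "ct": np.nan if ct > max_cycles else float(ct),
                    }
                )
    return pd.DataFrame(rows, columns=["sample", "gene", "prep", "replicate", "ct"])


# ---------------------------------------------------------------------------
# File output


def write_fasta(spec: LocusSpec, path: str, seed: int | None = None) -> None:
    desc = f"window={format_region(spec.window)} (sequence covers this window only)"
    if seed is not None:
        desc += f" seed={seed}"
    with open(path, "w") as fh:
        fh.write(f">{spec.window.chrom} {desc}\n")
        for i in range(0, len(spec.sequence), 80):
            fh.write(spec.sequence[i : i + 80] + "\n")


def write_sam(records: list[pysam.AlignedSegment], header: pysam.AlignmentHeader, path: str) -> None:
    with pysam.AlignmentFile(path, "wh", header=header) as fh:
        for rec in records:
            fh.write(rec)


def read_sam(path: str) -> tuple[list[pysam.AlignedSegment], pysam.AlignmentHeader]:
    with pysam.AlignmentFile(path, "r") as fh:
        records = list(fh)
        return records, fh.header


def write_truth(truth: pd.DataFrame, path: str, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        truth.to_csv(fh, sep="\t", index=False)
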