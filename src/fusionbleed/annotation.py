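"""Gene models, exon-overlap interval algebra and the exon-sharing census.

The central question this module answers is: which exonic bases of a
transcript are *unique* to it, and which are *shared* with transcripts of
other genes?  Reads falling in shared bases are ambiguous under
multi-assignment quantification, so partitioning a transcript's exonic
footprint into unique and shared segments is the prerequisite both for
diagnosing misassignment and for the unique-region estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, merge_intervals, total_length

log = logging.getLogger(__name__)


class GtfParseError(ValueError):
    """Raised for malformed GTF input; message names the offending line."""


class UnknownTranscriptError(KeyError):
    """Raised when a transcript id is not present in an Annotation."""


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered set of exons on one strand.

    ``exons`` are in genomic order (sorted by start), pairwise
    non-overlapping, and share chrom and strand.  Transcription order on the
    '-' strand is the reverse of genomic order.
    """

    transcript_id: str
    gene_id: str
    biotype: str
    exons: tuple[GenomicInterval, ...]
    strand: str

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        object.__setattr__(self, "exons", tuple(self.exons))
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != self.chrom or ex.strand not in (self.strand, "."):
                raise ValueError(
                    f"transcript {self.transcript_id}: exons must share chrom/strand"
                )
            if ex.start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def spliced_length(self) -> int:
        return total_length(self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    def exons_in_transcription_order(self) -> tuple[GenomicInterval, ...]:
        return self.exons if self.strand != "-" else tuple(reversed(self.exons))

    def spliced_to_genomic(self, start: int, end: int) -> list[GenomicInterval]:
        """Project a spliced-coordinate interval [start, end) onto the genome.

        Spliced coordinates run in transcription order (position 0 is the 5'
        end of the mature transcript).  Returns disjoint genomic blocks in
        genomic order; their lengths sum to ``end - start``.
        """
        if not (0 <= start < end <= self.spliced_length):
            raise ValueError(
                f"spliced interval [{start}, {end}) outside transcript "
                f"{self.transcript_id} of length {self.spliced_length}"
            )
        blocks: list[GenomicInterval] = []
        offset = 0
        for ex in self.exons_in_transcription_order():
            lo = max(start, offset)
            hi = min(end, offset + ex.length)
            if lo < hi:
                if self.strand == "-":
                    # spliced position offset maps to genomic ex.end - 1
                    g_end = ex.end - (lo - offset)
                    g_start = ex.end - (hi - offset)
                else:
                    g_start = ex.start + (lo - offset)
                    g_end = ex.start + (hi - offset)
                blocks.append(GenomicInterval(ex.chrom, g_start, g_end, self.strand))
            offset += ex.length
        return sorted(blocks, key=lambda b: b.start)


@dataclass(frozen=True)
class Segment:
    """One maximal run of a transcript's exonic footprint with uniform status."""

    interval: GenomicInterval
    status: str  # "unique" | "shared"
    sharer_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.status not in ("unique", "shared"):
            raise ValueError(f"bad segment status {self.status!r}")
        if (self.status == "shared") != bool(self.sharer_ids):
            raise ValueError("status 'shared' iff sharer_ids non-empty")


@dataclass(frozen=True)
class RegionPartition:
    """A transcript's exonic footprint split into unique and shared segments."""

    transcript_id: str
    segments: tuple[Segment, ...]

    @property
    def unique_intervals(self) -> list[GenomicInterval]:
        return [s.interval for s in self.segments if s.status == "unique"]

    @property
    def shared_intervals(self) -> list[GenomicInterval]:
        return [s.interval for s in self.segments if s.status == "shared"]

    @property
    def unique_length(self) -> int:
        return total_length(self.unique_intervals)

    @property
    def shared_length(self) -> int:
        return total_length(self.shared_intervals)


@dataclass
class Annotation:
    """A set of gene models with an interval index over all exons.

    ``genes`` maps gene_id -> (gene_name, biotype, transcripts).  The index
    answers "which exons intersect this interval?" and is used by the
    partitioner, the census and fragment assignment.
    """

    genes: dict[str, tuple[str, str, list[TranscriptModel]]] = field(default_factory=dict)
    _by_tid: dict[str, TranscriptModel] = field(default_factory=dict, repr=False)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    @classmethod
    def from_transcripts(
        cls,
        transcripts: Iterable[TranscriptModel],
        gene_names: Mapping[str, str] | None = None,
        gene_biotypes: Mapping[str, str] | None = None,
    ) -> "Annotation":
        ann = cls()
        for t in transcripts:
            name = (gene_names or {}).get(t.gene_id, t.gene_id)
            biotype = (gene_biotypes or {}).get(t.gene_id, t.biotype)
            ann.add_transcript(t, gene_name=name, gene_biotype=biotype)
        return ann

    def add_transcript(
        self, t: TranscriptModel, gene_name: str | None = None, gene_biotype: str | None = None
    ) -> None:
        if t.transcript_id in self._by_tid:
            raise ValueError(f"duplicate transcript id {t.transcript_id}")
        if t.gene_id not in self.genes:
            self.genes[t.gene_id] = (gene_name or t.gene_id, gene_biotype or t.biotype, [])
        self.genes[t.gene_id][2].append(t)
        self._by_tid[t.transcript_id] = t
        tree = self._trees.setdefault(t.chrom, IntervalTree())
        for ex in t.exons:
            tree.addi(ex.start, ex.end, (t.transcript_id, t.gene_id, t.strand))

    @property
    def transcripts(self) -> list[TranscriptModel]:
        return sorted(self._by_tid.values(), key=lambda t: t.transcript_id)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_tid

    def transcript(self, transcript_id: str) -> TranscriptModel:
        try:
            return self._by_tid[transcript_id]
        except KeyError:
            raise UnknownTranscriptError(transcript_id) from None

    def gene_of(self, transcript_id: str) -> str:
        return self.transcript(transcript_id).gene_id

    def query_exons(
        self, iv: GenomicInterval
    ) -> list[tuple[GenomicInterval, str, str]]:
        """All exons intersecting ``iv``: (exon, transcript_id, gene_id)."""
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        hits = []
        for node in tree.overlap(iv.start, iv.end):
            tid, gid, strand = node.data
            hits.append((GenomicInterval(iv.chrom, node.begin, node.end, strand), tid, gid))
        hits.sort(key=lambda h: (h[0].start, h[0].end, h[1]))
        return hits


# ---------------------------------------------------------------------------
# GTF I/O

_REQUIRED_GTF_COLUMNS = 9


def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise GtfParseError(f"line {lineno}: cannot parse attribute {chunk!r}")
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str) -> Annotation:
    """Read exon records from a GTF file into an :class:`Annotation`.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    Only ``exon`` features are used; everything else (gene, transcript, CDS,
    UTR lines) is ignored.  Biotype is taken from ``transcript_biotype``,
    falling back to ``gene_biotype``, then to ``"unknown"``.
    """
    per_tid: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _REQUIRED_GTF_COLUMNS:
                raise GtfParseError(
                    f"line {lineno}: expected {_REQUIRED_GTF_COLUMNS} tab-separated "
                    f"columns, found {len(fields)}"
                )
            chrom, _source, feature, start1, end1, _score, strand, _frame, attr_text = fields
            if feature != "exon":
                continue
            try:
                start = int(start1) - 1
                end = int(end1)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
            if start < 0 or end <= start:
                raise GtfParseError(f"line {lineno}: invalid coordinates {start1}-{end1}")
            attrs = _parse_attributes(attr_text, lineno)
            if "transcript_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon record lacks transcript_id")
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon record lacks gene_id")
            tid = attrs["transcript_id"]
            rec = per_tid.setdefault(
                tid,
                {
                    "gene_id": attrs["gene_id"],
                    "gene_name": attrs.get("gene_name", attrs["gene_id"]),
                    "biotype": attrs.get(
                        "transcript_biotype", attrs.get("gene_biotype", "unknown")
                    ),
                    "strand": strand if strand in ("+", "-") else ".",
                    "exons": [],
                },
            )
            rec["exons"].append(GenomicInterval(chrom, start, end, rec["strand"]))
    ann = Annotation()
    for tid, rec in per_tid.items():
        exons = sorted(rec["exons"], key=lambda iv: iv.start)
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            biotype=rec["biotype"],
            exons=tuple(exons),
            strand=rec["strand"],
        )
        ann.add_transcript(t, gene_name=rec["gene_name"], gene_biotype=rec["biotype"])
    return ann


def write_gtf(ann: Annotation, path: str, source: str = "fusionbleed") -> None:
    """Write exon records (1-based inclusive) for all transcripts."""
    with open(path, "w") as fh:
        for t in ann.transcripts:
            gene_name = ann.genes[t.gene_id][0]
            for ex in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_name "{gene_name}"; gene_biotype "{t.biotype}"; '
                    f'transcript_biotype "{t.biotype}";'
                )
                fh.write(
                    "\t".join(
                        [
                            ex.chrom,
                            source,
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            t.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Interval algebra


def exonic_union(t: TranscriptModel | Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal sorted disjoint interval list covering a transcript's exon bases.

    For a valid :class:`TranscriptModel` (disjoint sorted exons) the union is
    the exon list itself (adjacent exons merge); raw interval lists with
    overlaps are also accepted and merged.
    """
    exons = t.exons if isinstance(t, TranscriptModel) else tuple(t)
    return merge_intervals(exons)


def _strand_compatible(a: str, b: str, same_strand: bool) -> bool:
    if not same_strand:
        return True
    return a == b or a == "." or b == "."


def partition_unique_shared(
    t: TranscriptModel,
    ann: Annotation,
    cross_gene_only: bool = True,
    same_strand: bool = True,
) -> RegionPartition:
    """Label every exonic base of ``t`` unique or shared.

    A base is *shared* when it is covered by an exon of another transcript —
    of another gene when ``cross_gene_only`` (the default, matching the
    cross-gene misassignment problem), of any other transcript otherwise.
    ``same_strand`` restricts sharers to the transcript's strand.  Adjacent
    bases with the same status and the same sharer set are merged into
    maximal segments; segments exactly tile the exonic union.
    """
    if t.transcript_id not in ann:
        raise UnknownTranscriptError(t.transcript_id)
    union = exonic_union(t)
    segments: list[Segment] = []
    for uiv in union:
        hits = []
        for exon, tid, gid in ann.query_exons(uiv):
            if tid == t.transcript_id:
                continue
            if cross_gene_only and gid == t.gene_id:
                continue
            if not _strand_compatible(exon.strand, t.strand, same_strand):
                continue
            hits.append((exon, tid))
        points = {uiv.start, uiv.end}
        for exon, _tid in hits:
            points.add(min(max(exon.start, uiv.start), uiv.end))
            points.add(min(max(exon.end, uiv.start), uiv.end))
        bounds = sorted(points)
        run_start = None
        run_sharers: frozenset[str] = frozenset()
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            sharers = frozenset(
                tid for exon, tid in hits if exon.start < hi and lo < exon.end
            )
            if run_start is None:
                run_start, run_sharers = lo, sharers
            elif sharers != run_sharers:
                segments.append(_make_segment(uiv, run_start, lo, run_sharers))
                run_start, run_sharers = lo, sharers
        if run_start is not None:
            segments.append(_make_segment(uiv, run_start, uiv.end, run_sharers))
    return RegionPartition(transcript_id=t.transcript_id, segments=tuple(segments))


def _make_segment(
    uiv: GenomicInterval, start: int, end: int, sharers: frozenset[str]
) -> Segment:
    iv = GenomicInterval(uiv.chrom, start, end, uiv.strand)
    status = "shared" if sharers else "unique"
    return Segment(interval=iv, status=status, sharer_ids=sharers)


# ---------------------------------------------------------------------------
# Exon-sharing census


def _passes_biotype(t: TranscriptModel, biotype: str | None) -> bool:
    return biotype is None or t.biotype == biotype


def _share_exonic_bases(
    a: TranscriptModel,
    b: TranscriptModel,
    same_strand: bool,
    min_overlap: int,
    boundary_identity: bool,
) -> bool:
    if a.chrom != b.chrom:
        return False
    if not _strand_compatible(a.strand, b.strand, same_strand):
        return False
    if boundary_identity:
        return bool({(e.start, e.end) for e in a.exons} & {(e.start, e.end) for e in b.exons})
    shared = sum(ea.intersection_length(eb) for ea in a.exons for eb in b.exons)
    return shared >= min_overlap


def find_exon_sharing_transcripts(
    ann: Annotation,
    biotype: str | None = "protein_coding",
    same_strand: bool = True,
    min_overlap: int = 1,
    boundary_identity: bool = False,
) -> list[tuple[str, list[str]]]:
    """Census of transcripts sharing exonic sequence across genes.

    Returns ``(transcript_id, sorted partner ids)`` for every transcript
    passing the biotype filter that overlaps (>= ``min_overlap`` exonic bases,
    or an identical exon when ``boundary_identity``) a transcript of a
    *different* gene; the relation is symmetric.  ``biotype=None`` disables
    the filter (default mirrors a protein-coding census).
    """
    candidates = [t for t in ann.transcripts if _passes_biotype(t, biotype)]
    partners: dict[str, set[str]] = {}
    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            if a.gene_id == b.gene_id:
                continue
            if not a.span.overlaps(b.span):
                continue
            if _share_exonic_bases(a, b, same_strand, min_overlap, boundary_identity):
                partners.setdefault(a.transcript_id, set()).add(b.transcript_id)
                partners.setdefault(b.transcript_id, set()).add(a.transcript_id)
    return [(tid, sorted(p)) for tid, p in sorted(partners.items())]


def contributing_transcripts_report(
    ann: Annotation, same_strand: bool = True
) -> pd.DataFrame:
    """One row per transcript listing other genes' transcripts that can
    contribute to its signal, with the shared exonic base count for each.

    Columns: gene_id, transcript_id, contributors (comma-joined
    ``tid=bases``, empty when none), total_shared_bases.  Rows are ordered by
    (gene_id, transcript_id); contributors lexicographically.
    """
    rows = []
    transcripts = ann.transcripts
    for t in transcripts:
        contribs: list[tuple[str, int]] = []
        for other in transcripts:
            if other.gene_id == t.gene_id:
                continue
            if not _strand_compatible(other.strand, t.strand, same_strand):
                continue
            shared = sum(
                ea.intersection_length(eb)
                for ea in exonic_union(t)
                for eb in exonic_union(other)
            )
            if shared > 0:
                contribs.append((other.transcript_id, shared))
        contribs.sort()
        rows.append(
            {
                "gene_id": t.gene_id,
                "transcript_id": t.transcript_id,
                "contributors": ",".join(f"{tid}={n}" for tid, n in contribs),
                "total_shared_bases": sum(n for _tid, n in contribs),
            }
        )
    df = pd.DataFrame(rows, columns=["gene_id", "transcript_id", "contributors", "total_shared_bases"])
    return df.sort_values(["gene_id", "transcript_id"], ignore_index=True)
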