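"""Per-base read depth over a genomic window, with filtering and capping.

This reimplements the classic depth re-analysis workflow: filter alignments
on mate orientation, insert size and mapping quality, then count, at every
base of a window, how many reads' aligned blocks cover it (intron-skip
blocks do not count).  Depth tracks can be capped — some published coverage
tracks clamp depth (at 8,000 in the study this package models) — and
exported as bedGraph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import RegionPartition
from .intervals import GenomicInterval, format_region


@dataclass(frozen=True)
class AlignmentFilter:
    """Alignment-level filters: mapping quality, insert size, orientation.

    Defaults follow the re-analysis this package models: minimum mapping
    quality 10, maximum insert 500,000 bases, inward-facing proper pairs
    required.
    """

    min_mapq: int = 10
    max_insert: int = 500_000
    require_proper_orientation: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        if self.max_insert <= 0:
            raise ValueError("max_insert must be > 0")


@dataclass
class DepthTrack:
    """Per-base depth over a window; ``cap`` records any clamp applied."""

    window: GenomicInterval
    depth: np.ndarray
    cap: int | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if len(self.depth) != self.window.length:
            raise ValueError("depth array length must equal window length")
        if (self.depth < 0).any():
            raise ValueError("depth values must be >= 0")
        if self.cap is not None and (self.depth > self.cap).any():
            raise ValueError("depth values exceed declared cap")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepthTrack):
            return NotImplemented
        return (
            self.window == other.window
            and self.cap == other.cap
            and np.array_equal(self.depth, other.depth)
        )


def _orientation_ok(rec: pysam.AlignedSegment) -> bool:
    """Inward-facing pair: mates on opposite strands, forward mate leftmost."""
    if not rec.is_paired or rec.mate_is_unmapped or rec.is_unmapped:
        return False
    if rec.is_reverse == rec.mate_is_reverse:
        return False
    if rec.reference_id != rec.next_reference_id:
        return False
    if rec.is_reverse:
        return rec.next_reference_start <= rec.reference_start
    return rec.reference_start <= rec.next_reference_start


def filter_alignments(
    records: Iterable[pysam.AlignedSegment], f: AlignmentFilter = AlignmentFilter()
) -> list[pysam.AlignedSegment]:
    """Keep records passing mapping-quality, insert-size and orientation filters.

    Order is preserved.  A record that is not an AlignedSegment raises
    ``TypeError`` naming it.
    """
    kept = []
    for rec in records:
        if not isinstance(rec, pysam.AlignedSegment):
            raise TypeError(f"not an alignment record: {rec!r}")
        if rec.mapping_quality < f.min_mapq:
            continue
        if abs(rec.template_length) > f.max_insert:
            continue
        if f.require_proper_orientation and not _orientation_ok(rec):
            continue
        kept.append(rec)
    return kept


def compute_depth(
    records: Iterable[pysam.AlignedSegment],
    window: GenomicInterval,
    cap: int | None = None,
) -> DepthTrack:
    """Per-base depth: number of records whose aligned blocks cover each base.

    Each read of a pair counts independently (overlapping mates count
    twice), matching samtools-style depth semantics; intron-skip (N) blocks
    contribute nothing.  Records on other chromosomes are ignored; values
    are clipped at ``cap`` when set.
    """
    depth = np.zeros(window.length, dtype=np.int64)
    ref = window.chrom
    for rec in records:
        if rec.is_unmapped or rec.reference_name != ref:
            continue
        for bs, be in rec.get_blocks():
            lo = max(bs, window.start) - window.start
            hi = min(be, window.end) - window.start
            if lo < hi:
                depth[lo:hi] += 1
    if cap is not None:
        np.minimum(depth, cap, out=depth)
    return DepthTrack(window=window, depth=depth, cap=cap)


def collapse_mates(records: Iterable[pysam.AlignedSegment]) -> list[pysam.AlignedSegment]:
    """Optionally pre-collapse pairs to one record per fragment (first mate).

    Using this before :func:`compute_depth` gives fragment depth instead of
    read depth; bases covered by both mates then count once.  Note the
    surviving record still only carries its own blocks.
    """
    return [r for r in records if not (r.is_paired and r.is_read2)]


def region_summary(track: DepthTrack, part: RegionPartition) -> pd.DataFrame:
    """Depth statistics per partition segment plus per-status aggregates.

    One row per segment (columns: segment, status, length, mean_depth,
    median_depth, summed_depth) followed by one aggregate row per status
    present; summed depths of a status' segments add up to its aggregate.
    """
    rows = []
    by_status: dict[str, list[np.ndarray]] = {}
    for seg in part.segments:
        iv = seg.interval
        if iv.start < track.window.start or iv.end > track.window.end:
            raise ValueError(f"segment {iv} outside depth window {track.window}")
        vals = track.depth[iv.start - track.window.start : iv.end - track.window.start]
        by_status.setdefault(seg.status, []).append(vals)
        rows.append(
            {
                "segment": str(iv),
                "status": seg.status,
                "length": iv.length,
                "mean_depth": float(vals.mean()),
                "median_depth": float(np.median(vals)),
                "summed_depth": int(vals.sum()),
            }
        )
    for status in sorted(by_status):
        vals = np.concatenate(by_status[status])
        rows.append(
            {
                "segment": f"all_{status}",
                "status": status,
                "length": int(len(vals)),
                "mean_depth": float(vals.mean()),
                "median_depth": float(np.median(vals)),
                "summed_depth": int(vals.sum()),
            }
        )
    return pd.DataFrame(
        rows, columns=["segment", "status", "length", "mean_depth", "median_depth", "summed_depth"]
    )


# ---------------------------------------------------------------------------
# bedGraph I/O


def write_bedgraph(track: DepthTrack, path: str, extra_comments: Sequence[str] = ()) -> None:
    """Run-length-encoded 4-column bedGraph; zero runs are omitted.

    The window and cap are recorded in header comments so the round trip is
    lossless including leading/trailing zero stretches.
    """
    with open(path, "w") as fh:
        fh.write(f"# window={format_region(track.window)}\n")
        fh.write(f"# cap={'none' if track.cap is None else track.cap}\n")
        for comment in extra_comments:
            fh.write(f"# {comment}\n")
        depth = track.depth
        boundaries = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(depth)]))
        for s, e in zip(starts, ends):
            v = int(depth[s])
            if v != 0:
                fh.write(
                    f"{track.window.chrom}\t{track.window.start + s}\t{track.window.start + e}\t{v}\n"
                )


class BedGraphFormatError(ValueError):
    pass


def read_bedgraph(path: str) -> DepthTrack:
    """Read a bedGraph written by :func:`write_bedgraph`.

    Intervals must be non-overlapping; overlap raises
    :class:`BedGraphFormatError`.  Without a ``# window=`` header comment the
    window is inferred from the data lines.
    """
    window: GenomicInterval | None = None
    cap: int | None = None
    lines: list[tuple[str, int, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ").strip()
                if body.startswith("window="):
                    from .intervals import parse_region

                    window = parse_region(body.removeprefix("window="))
                elif body.startswith("cap="):
                    value = body.removeprefix("cap=")
                    cap = None if value == "none" else int(value)
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise BedGraphFormatError(f"line {lineno}: expected 4 columns")
            chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), int(fields[3])
            lines.append((chrom, s, e, v))
    if window is None:
        if not lines:
            raise BedGraphFormatError("no window header and no data lines")
        window = GenomicInterval(lines[0][0], min(l[1] for l in lines), max(l[2] for l in lines))
    depth = np.zeros(window.length, dtype=np.int64)
    prev_end = -1
    for chrom, s, e, v in sorted(lines, key=lambda l: l[1]):
        if chrom != window.chrom:
            raise BedGraphFormatError(f"chromosome {chrom} does not match window {window.chrom}")
        if s < prev_end:
            raise BedGraphFormatError(f"overlapping intervals at {chrom}:{s}")
        if s < window.start or e > window.end:
            raise BedGraphFormatError(f"interval {chrom}:{s}-{e} outside window")
        depth[s - window.start : e - window.start] = v
        prev_end = e
    return DepthTrack(window=window, depth=depth, cap=cap)
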