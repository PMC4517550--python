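"""Splice-variant-specific primer verification.

Two routes to specificity are provided.  ``unique_segments_by_alignment``
delineates the sequence unique to one transcript relative to another via
global (Needleman-Wunsch) alignment — the step used to pick primer regions
that distinguish a fusion transcript from its parent gene.  ``find_amplicons``
and ``specificity_check`` then verify a primer pair by in-silico PCR: exact
forward/reverse site matching on each transcript's spliced sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio.Seq import reverse_complement

from .annotation import Annotation

_VALID_PRIMER = re.compile(r"^[ACGT]{10,}$")


@dataclass(frozen=True)
class PrimerPair:
    """A qPCR primer pair in the sense of the target transcript."""

    name: str
    forward: str
    reverse: str
    intended_target: str

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if not _VALID_PRIMER.match(seq):
                raise ValueError(
                    f"primer {self.name}: sequences must be >=10 bases over ACGT, got {seq!r}"
                )


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on a transcript's spliced sequence."""

    transcript_id: str
    start: int  # 0-based, start of the forward primer site
    end: int    # exclusive, end of the reverse primer site

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SpecificityVerdict:
    verdict: str  # "specific" | "cross-amplifying" | "non-amplifying"
    amplicons: tuple[Amplicon, ...]
    notes: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Global alignment

_MATCH, _MISMATCH, _GAP = 1, -1, -2
_DIAG, _UP, _LEFT = 0, 1, 2


def needleman_wunsch(seq_a: str, seq_b: str) -> tuple[int, list[tuple[int | None, int | None]]]:
    """Global alignment with linear gaps (match +1, mismatch -1, gap -2).

    Returns (score, columns) where each column is (i, j): indices into
    seq_a/seq_b, or None for a gap.  Traceback ties are broken
    deterministically: diagonal, then up (gap in seq_b), then left.
    """
    n, m = len(seq_a), len(seq_b)
    if n == 0 or m == 0:
        raise ValueError("sequences must be non-empty")
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    F = np.empty((n + 1, m + 1), dtype=np.int32)
    P = np.empty((n + 1, m + 1), dtype=np.int8)
    F[0, :] = _GAP * np.arange(m + 1)
    F[:, 0] = _GAP * np.arange(n + 1)
    P[0, :] = _LEFT
    P[:, 0] = _UP
    j_all = np.arange(m + 1)
    j_idx = j_all[1:]
    for i in range(1, n + 1):
        sub = np.where(a[i - 1] == b, _MATCH, _MISMATCH)
        diag = F[i - 1, :-1] + sub
        up = F[i - 1, 1:] + _GAP
        cand = np.maximum(diag, up)
        # Left-gap relaxation with a linear gap cost is a running maximum:
        # F[i, j] = max_{k<=j} (v_k + _GAP*(j-k)) where v_0 = F[i, 0] and
        # v_k = cand[k] for k >= 1.
        vals = np.concatenate(([F[i, 0]], cand))
        run = np.maximum.accumulate(vals - _GAP * j_all)
        F[i, 1:] = run[1:] + _GAP * j_idx
        row = F[i, 1:]
        P[i, 1:] = np.where(row == diag, _DIAG, np.where(row == up, _UP, _LEFT))
    score = int(F[n, m])
    cols: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        p = P[i, j]
        if i > 0 and j > 0 and p == _DIAG:
            cols.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and p == _UP:
            cols.append((i - 1, None))
            i -= 1
        else:
            cols.append((None, j - 1))
            j -= 1
    cols.reverse()
    return score, cols


def unique_segments_by_alignment(seq_a: str, seq_b: str, min_run: int = 20) -> list[tuple[int, int]]:
    """Maximal runs of seq_a positions not identity-aligned to seq_b.

    Globally aligns the two sequences and returns 0-based half-open
    intervals on ``seq_a`` (length >= ``min_run``) whose positions align to a
    mismatch or a gap — the sequence "unique" to seq_a, i.e. candidate
    regions for variant-specific primers.
    """
    _score, cols = needleman_wunsch(seq_a, seq_b)
    unique_flags = np.zeros(len(seq_a), dtype=bool)
    for i, j in cols:
        if i is None:
            continue
        unique_flags[i] = j is None or seq_a[i] != seq_b[j]
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(unique_flags):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_run:
                runs.append((start, i))
            start = None
    if start is not None and len(seq_a) - start >= min_run:
        runs.append((start, len(seq_a)))
    return runs


# ---------------------------------------------------------------------------
# In-silico PCR


def _find_all(haystack: str, needle: str) -> list[int]:
    out, pos = [], haystack.find(needle)
    while pos != -1:
        out.append(pos)
        pos = haystack.find(needle, pos + 1)
    return out


def find_amplicons(
    p: PrimerPair, transcript_seqs: dict[str, str], max_amplicon: int = 1000
) -> list[Amplicon]:
    """All exact-match amplicons of a primer pair across transcript sequences.

    An amplicon requires the forward primer on the sense strand and the
    reverse complement of the reverse primer downstream, with total span at
    most ``max_amplicon`` and at least the longer primer.  All valid
    (forward site, reverse site) combinations are reported.
    """
    rc_rev = reverse_complement(p.reverse)
    min_len = max(len(p.forward), len(p.reverse))
    amplicons = []
    for tid in sorted(transcript_seqs):
        seq = transcript_seqs[tid]
        fwd_sites = _find_all(seq, p.forward)
        rev_sites = _find_all(seq, rc_rev)
        for f in fwd_sites:
            for r in rev_sites:
                end = r + len(rc_rev)
                if r >= f and min_len <= end - f <= max_amplicon:
                    amplicons.append(Amplicon(transcript_id=tid, start=f, end=end))
    return amplicons


def specificity_check(
    p: PrimerPair,
    transcript_seqs: dict[str, str],
    ann: Annotation,
    max_amplicon: int = 1000,
) -> SpecificityVerdict:
    """Judge a primer pair: specific, cross-amplifying or non-amplifying.

    The pair is *specific* when it amplifies its intended target and no
    transcript of another gene; amplicons in other transcripts of the same
    gene (splice variants sharing the region) are tolerated and reported in
    the notes.  Any amplicon in another gene's transcript makes the verdict
    *cross-amplifying* — signal there would be indistinguishable from the
    target's.  No amplicon anywhere is *non-amplifying*.
    """
    if p.intended_target not in transcript_seqs:
        raise KeyError(f"intended target {p.intended_target!r} not among transcript sequences")
    amplicons = tuple(find_amplicons(p, transcript_seqs, max_amplicon=max_amplicon))
    if not amplicons:
        return SpecificityVerdict("non-amplifying", amplicons)
    target_gene = ann.gene_of(p.intended_target)
    in_target = [a for a in amplicons if a.transcript_id == p.intended_target]
    cross_gene = [a for a in amplicons if ann.gene_of(a.transcript_id) != target_gene]
    same_gene_other = [
        a
        for a in amplicons
        if a.transcript_id != p.intended_target and ann.gene_of(a.transcript_id) == target_gene
    ]
    notes = tuple(
        f"also amplifies same-gene transcript {a.transcript_id} "
        f"({a.start}-{a.end}, {a.length} bp)"
        for a in same_gene_other
    )
    if not in_target or cross_gene:
        return SpecificityVerdict("cross-amplifying", amplicons, notes)
    return SpecificityVerdict("specific", amplicons, notes)


# ---------------------------------------------------------------------------
# Primer set I/O


def read_primer_sets(path) -> list[PrimerPair]:
    """Read primer pairs from a TSV with columns name, forward, reverse, target."""
    pairs = []
    with open(path) as fh:
        header: list[str] | None = None
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            rec = dict(zip(header, fields))
            pairs.append(
                PrimerPair(
                    name=rec["name"],
                    forward=rec["forward"],
                    reverse=rec["reverse"],
                    intended_target=rec["target"],
                )
            )
    return pairs


def load_packaged_primer_sets() -> list[PrimerPair]:
    """The published primer sets shipped with the package."""
    ref = resources.files("fusionbleed.data") / "primer_sets.tsv"
    with resources.as_file(ref) as path:
        return read_primer_sets(path)


def read_fasta_sequences(path) -> dict[str, str]:
    """Read transcript sequences from FASTA (id -> uppercase sequence)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
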