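# Methods

## The problem being modelled

Overlapping genes and read-through (fusion) transcripts create ambiguity in
expression estimation: a sequenced fragment lying in exonic sequence common
to transcripts of two genes is evidence for either. Pipelines that assign
such fragments to every compatible transcript ("multi-assignment") make a
rare fusion transcript inherit the signal of its abundant parent gene. The
INS/INS-IGF2 locus is the extreme case: INS mRNA dominates the beta-cell
transcript pool, the INS-IGF2 read-through shares INS's first coding exon,
and the fusion's apparent expression under multi-assignment is set almost
entirely by that shared exon, differing from the parent mainly through
length normalisation.

## Coordinates and interval algebra

All intervals are 0-based half-open internally; GTF (1-based inclusive) and
`chrom:start-end` region strings are converted at I/O. A transcript is an
ordered list of disjoint exons on one strand; its **region partition**
labels every exonic base `unique` or `shared` depending on whether any exon
of another gene's transcript covers it (same-strand by default — the
modelled locus is entirely antisense — with an option to ignore strand;
`cross_gene_only=False` extends sharing to sibling isoforms). Partitioning
is a boundary sweep over the exons returned by an interval-tree index and is
validated in the test suite against a per-base brute-force oracle, as is the
index against a linear scan.

"Sharing exons" for the census is operationalised as ≥ 1 bp of exonic
overlap between transcripts of distinct genes on the same strand, because
exact exon-boundary identity is a stricter claim than misassignment
requires; both the minimum overlap and a boundary-identity mode are exposed
as options, as is disabling the strand requirement. The census defaults to
the `protein_coding` biotype. The absolute size of such a census is
annotation-version dependent, so no particular count is asserted anywhere;
the procedure, not a number, is the deliverable.

## Synthetic locus and read simulator

`build_default_locus` places three antisense transcripts in a 40 kb window
(coordinates chosen inside the chr11 region the real locus occupies):

| transcript | exons (length) | spliced | role |
|---|---|---|---|
| INS-like | B 400, A 600 | 1,000 | short, abundant; exon A shared |
| INS-IGF2-like | distal 600, mid 900, A 600 | 2,100 | long, rare fusion |
| IGF2-like | 800, 700, 500 | 2,000 | non-overlapping control |

Default molar abundances are 20,000 : 1 : 4 (INS-like : fusion :
IGF2-like). The 20,000 : 1 ratio is the regime the qPCR table establishes
for the real locus; the IGF2-like value mirrors the measured islet
IGF2-to-INS ratio (≈ 2 × 10⁻⁴ of 20,000). Background sequence is uniform
random ACGT from the seed; the three published variant-specific primer
pairs are embedded at topologically corresponding spliced positions (set 1
spanning the short gene's exon A/B junction into unique sequence, set 2
inside the fusion's middle unique exon, set 3 inside the control gene), so
primer specificity on the synthetic locus is known by construction.

Fragments are drawn per transcript with probability ∝ abundance ×
effective length (spliced length − mean fragment length + 1, floored at 1):
the molar-abundance model under which longer transcripts capture
proportionally more fragments, which is the mechanism behind the
length-normalisation part of the artefact. The spliced start is uniform
over valid positions; the fragment length is normal truncated to
[read length, spliced length] (scipy `truncnorm`). Defaults — fragment mean
300 bp, SD 30, reads 2 × 75 bp — are ordinary bulk-RNA-seq library values;
no fragment statistics are published for the data being modelled, so these
are configurable. Mates are emitted inward-facing with MAPQ 60 so the
orientation and quality filters are exercised; transcripts shorter than the
read length are excluded with a warning. Each record carries its true
transcript of origin in the `XT` tag and the truth table has one row per
fragment. Sequencing errors and quality strings are deliberately omitted:
the artefact is a property of assignment, not base-calling.

## Depth analysis

`filter_alignments` reimplements the published re-analysis filter: mapping
quality ≥ 10, |template length| ≤ 500,000, inward-facing properly-oriented
pairs; all thresholds are parameters. `compute_depth` counts, per base of a
window, the reads whose aligned match blocks cover it — intron skips
contribute nothing, and the two mates of a pair count independently
(classic samtools-style depth; a collapse-mates helper gives fragment
depth instead). Depth can be clamped, mirroring the 8,000-read cap observed
in the published coverage track; the cap defaults to off. Tracks serialise
as run-length-encoded bedGraph with the window and cap in header comments
so the round trip is lossless including zero runs. No duplicate-read
removal is performed or claimed.

## Quantification

Compatibility uses exonic-union containment of every aligned block of both
mates. This is deliberately coarser than junction-chain matching: it is the
rule that produces the multi-assignment artefact being studied. A
`strict_junctions` mode additionally requires internal block boundaries to
coincide with consecutive exon junctions of the transcript, shrinking
compatible sets. Expression is reported as fragments per kilobase without
per-million scaling, since only within-dataset ratios carry meaning here.

The unique-region estimator counts fragments compatible with the
transcript that touch ≥ 1 unique base, normalised by unique length. On the
default locus geometry this estimator is unbiased for the abundance ratio:
the number of fragment start positions whose fragment reaches the unique
region equals the unique extent for both transcripts, so the ratio of
unique expressions has expectation equal to the abundance ratio, with
Poisson error dominated by the handful of fusion-unique fragments
(≈ 21 expected at 200,000 fragments). Transcripts with zero unique length
are flagged unquantifiable rather than given a value. A fragment touching
unique regions of two transcripts (possible only under within-gene
uniqueness) is credited to each.

## qPCR

Technical duplicates are averaged per preparation; ΔCt is taken against the
reference gene per preparation and averaged over preparations where both
values exist; relative expression against a reference transcript is
2^(−mean ΔΔCt) (geometric convention). The geometric convention is the one
that reproduces the packaged published table's printed ratios exactly from
its printed per-preparation values; mean-of-ratios averaging is available
as an option and differs whenever preparations disagree. Missing
amplification ("No Ct") is excluded pairwise and never imputed as the
cycle ceiling — the islet fusion row, with one No-Ct preparation, only
reproduces the printed value under exclusion. Amplification efficiency is
fixed at 100 % (one cycle = one doubling); no standard curves are modelled.
The inverse model (`simulate_ct`) maps abundance to
Ct = intercept − log₂(abundance) at efficiency 1, adds per-replicate
Gaussian noise, and records values above the cycle ceiling (default 40) as
missing; with zero noise the qPCR pipeline inverts it exactly, which is a
tested round trip.

Two internal inconsistencies of the published table are documented and not
targeted: its islet INS ΔCt (−6.31) differs in the second decimal from the
value recomputed from the printed preparations (−6.33, plausibly computed
from unrounded instrument values), and its EndoC fusion relative value
(0.000072) is not derivable from the printed Ct values under either
averaging convention (recomputation gives ≈ 0.000027).

## Primer verification

`unique_segments_by_alignment` delineates transcript-unique sequence by
global Needleman–Wunsch alignment (match +1, mismatch −1, linear gap −2;
ties broken diagonal > up > left), returning maximal runs of positions
aligned to a mismatch or gap. The scoring is the simplest standard scheme
and is configurable; no conclusion in the package depends on the score
values. A known limitation: for *diverged* (rather than inserted/deleted)
sequence, co-optimal alignments with accidental identities fragment the
runs, so run recovery is crisp for insertion-type uniqueness (a fusion's
extra exons vs the sequence it shares) and conservative otherwise; the
per-position unique/shared classification count remains exact. The DP is
row-vectorised in numpy and checked in the tests against an independent
plain-Python DP oracle and against Biopython's global aligner score.

In-silico PCR (`find_amplicons`) requires exact matches of the forward
primer and of the reverse complement of the reverse primer downstream, span
≤ 1,000 bp by default (ordinary qPCR practice); mismatch-tolerant matching
and melting-temperature modelling are out of scope. The specificity verdict
is gene-aware: amplicons in transcripts of another gene make the pair
cross-amplifying (their product is indistinguishable from the target's even
when the amplified sequence is identical, as inside a shared exon), while
amplicons in same-gene isoforms are tolerated and reported as notes. A pair
with no amplicon anywhere is non-amplifying.

## Problem sizes and numerical choices

The replicated artefact experiment uses ten seeds at 200,000 fragments —
enough that the naive/unique contrast is decided by orders of magnitude
while the whole experiment stays comfortably within an ordinary
single-core run; per-seed fusion-unique counts are small (~20), which the
3-standard-error recovery check accounts for. Property tests validate the
sweep-based partitioner, the depth engine and the aligner against
brute-force oracles on small inputs where the oracles are exact.
Determinism is part of the contract: every simulation consumes a single
`numpy` Generator seeded explicitly, and identical seeds produce
byte-identical FASTA/GTF/SAM/TSV outputs.

## What the synthetic universe does and does not show

The generator reproduces the *topology* and *abundance regime* that cause
the artefact, with known truth — so passing tests demonstrate that the
estimators behave as claimed under the stated sampling model. It does not
emulate sequencing error, positional or GC bias, fragment-length skew,
duplicate reads, multi-mapping ambiguity at the alignment stage, or real
INS/IGF2 sequence; conclusions about any particular real dataset still
require running the same diagnostics on that dataset. The exon-sharing
census on the synthetic locus validates the procedure, not any
genome-wide count, which varies with annotation release.
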