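# fusionbleed

Tools for diagnosing and correcting a common gene-expression artefact:
when a **fusion (read-through) transcript** shares exons with a highly
expressed gene, quantification pipelines that credit an ambiguous read to
*every* compatible transcript will inflate the fusion's apparent expression
by orders of magnitude. The canonical case is the INS-IGF2 read-through
transcript in pancreatic beta cells, which shares the first coding exon of
INS — one of the most abundant cell-type-specific mRNAs known — and was
consequently reported as one of the highest-expressed beta-cell transcripts
even though variant-specific qPCR places it >20,000-fold below INS.

The package is aimed at transcriptomics practitioners who want to (1) detect
loci at risk (exon-sharing census, contributing-transcripts report),
(2) reproduce the artefact and quantify its size on data with known truth,
and (3) apply the corrections: unique-region quantification, read-depth
inspection of unique vs shared segments, and splice-variant-specific qPCR.

## The model

Partition a transcript *t*'s exonic footprint into **unique** bases (covered
by no exon of any other gene's transcript) and **shared** bases. For a set of
sequenced fragments, a fragment is *compatible* with *t* when every aligned
block of both mates lies within *t*'s exonic union. Then

- **naive estimator** (the artefact):
  `E_naive(t) = #{fragments compatible with t} / L(t) × 1000`
  where `L(t)` is the spliced length — each ambiguous fragment is counted by
  every compatible transcript;
- **unique-region estimator** (the correction):
  `E_unique(t) = #{fragments compatible with t touching unique bases} / L_unique(t) × 1000`;
- **bleed-through index**: the fraction of *t*'s assigned fragments that are
  also compatible with another gene's transcript — near 1 means *t*'s
  apparent signal is borrowed.

For qPCR, relative expression uses the standard ΔΔCt model at 100 %
efficiency: per preparation *p*, ΔΔCt_p = Ct_target,p − Ct_reference,p, and
`rel = 2^(−mean_p ΔΔCt_p)` (the input-control ΔCt term cancels within a
preparation; "No Ct" preparations are excluded pairwise, never imputed).

Everything is exercisable without external data on a synthetic ~40 kb locus
with the hazardous topology: a short 2-exon gene (INS-like), a long rare
fusion sharing its first coding exon (INS-IGF2-like), and a clean
non-overlapping gene (IGF2-like), all antisense, with per-fragment ground
truth and the published primer binding sites embedded.

## Worked example

```python
import fusionbleed as fb
from fusionbleed.quantify import quantify_locus

spec = fb.build_default_locus(seed=1)              # truth: INS-like 20,000 : 1 fusion
records, truth = fb.simulate_reads(spec, 200_000, seed=1)
filtered = fb.filter_alignments(records)           # MAPQ>=10, insert<=500 kb, inward pairs
quant = quantify_locus(filtered, spec.annotation())
print(quant[["transcript_id", "naive_expression", "unique_expression",
             "bleedthrough_index"]].to_string(index=False))
```

```
    transcript_id  naive_expression  unique_expression  bleedthrough_index
    IGF2-like-001         46.500000               46.5            0.000000
INS-IGF2-like-001      40727.142857               16.0            0.999719
     INS-like-001     199883.000000           285950.0            0.427765
```

Reading: the naive estimator puts the fusion (40,727 fragments/kb) within a
factor of five of INS-like (199,883) although it is truly 20,000-fold rarer —
the artefact. The unique-region estimator gives 285,950 / 16.0 ≈ 17,900,
recovering the simulated ratio within Poisson error, and the bleed-through
index shows that 99.97 % of the fusion's assigned signal is ambiguous.

The qPCR side, from the packaged published per-preparation Ct table:

```python
from fusionbleed.qpcr import prep_means, relative_expression, fold_difference
pm = prep_means(fb.load_packaged_ct_table())
rel = relative_expression(pm, "INS-IGF2", "INS", "human_islets")
print(f"{rel:.6f}  ->  {fold_difference(rel):,.0f}-fold below INS")
# 0.000046  ->  21,619-fold below INS
```

The `examples/` directory holds one short narrative script per capability
(depth pattern, artefact + correction, qPCR table, primer specificity,
overlap census); each prints the numbers it computes and what they mean.
A thin CLI (`fusionbleed simulate|depth|quantify|qpcr|primers|overlap-scan|demo`)
wraps the same functions for shell use.

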