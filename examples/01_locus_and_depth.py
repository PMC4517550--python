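"""Build the synthetic locus, simulate reads and inspect the depth pattern.

The fusion transcript's unique exons receive almost no coverage while the
exon it shares with the short, highly expressed gene is buried in signal —
the visual signature that its apparent expression is borrowed.
"""

import fusionbleed as fb
from fusionbleed.annotation import partition_unique_shared
from fusionbleed.coverage import region_summary
from fusionbleed.locus import FUSION_TID

spec = fb.build_default_locus(seed=1)
print(f"window {spec.window}, {len(spec.transcripts)} transcripts, "
      f"abundances {spec.abundances}")

records, truth = fb.simulate_reads(spec, 20_000, seed=1)
filtered = fb.filter_alignments(records)  # MAPQ>=10, insert<=500 kb, inward pairs
track = fb.compute_depth(filtered, spec.window)

ann = spec.annotation()
part = partition_unique_shared(ann.transcript(FUSION_TID), ann)
summary = region_summary(track, part)
print(summary.to_string(index=False))

shared = summary.set_index("segment").loc["all_shared", "mean_depth"]
unique = summary.set_index("segment").loc["all_unique", "mean_depth"]
print(f"\nmean depth shared exon: {shared:.1f}; fusion-unique exons: {unique:.3f}")
print("-> the fusion's own exons are essentially empty; its signal sits in the shared exon.")
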