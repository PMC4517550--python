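"""Reproduce the quantification artefact and correct it.

With a true abundance ratio of 20,000 : 1, multi-assignment quantification
places the fusion transcript within one order of magnitude of the short
gene; restricting to unique regions recovers the truth.
"""

import math

import fusionbleed as fb
from fusionbleed.locus import FUSION_TID, INS_TID
from fusionbleed.quantify import quantify_locus

spec = fb.build_default_locus(seed=1)
records, _ = fb.simulate_reads(spec, 200_000, seed=1, with_sequence=False)
filtered = fb.filter_alignments(records)
quant = quantify_locus(filtered, spec.annotation()).set_index("transcript_id")
print(quant.to_string())

naive_gap = math.log10(quant.loc[INS_TID, "naive_expression"]
                       / quant.loc[FUSION_TID, "naive_expression"])
unique_ratio = (quant.loc[INS_TID, "unique_expression"]
                / quant.loc[FUSION_TID, "unique_expression"])
print(f"\nnaive estimator gap: {naive_gap:.2f} orders of magnitude "
      f"(truth: {math.log10(20_000):.2f})")
print(f"unique-region estimate of the ratio: {unique_ratio:,.0f}x (truth 20,000x)")
print(f"fusion bleed-through index: {quant.loc[FUSION_TID, 'bleedthrough_index']:.4f}")
print("-> nearly all of the fusion's assigned signal is ambiguous shared-exon signal.")
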