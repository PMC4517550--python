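"""Recompute the published qPCR table from its per-preparation Ct values.

ΔCt is each gene's Ct relative to the GAPDH input control; relative
expression is 2^(−ΔΔCt) against the INS transcript, averaged over
preparations (pairwise-complete: the islet preparation with no fusion
amplification is excluded, never imputed).
"""

import fusionbleed as fb
from fusionbleed.qpcr import (
    fold_difference, gapdh_normalize, prep_means, qpcr_summary, relative_expression,
    round_sigfig,
)

table = fb.load_packaged_ct_table()
summary = qpcr_summary(table, reference_gene="GAPDH", reference_transcript="INS")
print(summary.round(6).to_string(index=False))

pm = prep_means(table)
for sample in ("human_islets", "EndoC-bH1"):
    rel = relative_expression(pm, "INS-IGF2", "INS", sample)
    print(f"{sample}: fusion / INS = {rel:.6f} "
          f"-> {round_sigfig(fold_difference(rel), 1):,.0f}-fold lower (1 s.f.)")
print("-> the fusion transcript is >20,000-fold rarer than INS in both systems.")
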