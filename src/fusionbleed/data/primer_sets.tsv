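# Published qPCR primer sets: splice-variant-specific pairs for INS,
# INS-IGF2 and IGF2 plus the GAPDH input-control pair. Sequences are given
# in the sense of the target transcript (forward) and as the reverse
# complement of the target sense (reverse).
name	forward	reverse	target
Primerset1	GCAGGTGGAGCTGGGC	GGAGGAGAGGGACAAAGCTG	INS
Primerset2	CTACCTAGTGTGCGGGGAA	ATTGTTCCACAATGCCACGC	INS-IGF2
Primerset3	GATGCTGGTGCTTCTCACCT	CAGACGAACTGGAGGGTGTC	IGF2
GAPDH	AGGGCTGCTTTTAACTCTGGT	CCCCACTTGATTTTGGAGGGA	GAPDH
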