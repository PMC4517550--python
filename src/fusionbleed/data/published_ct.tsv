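# Published per-preparation mean Ct values for INS, INS-IGF2, IGF2 and GAPDH
# in human islets and the EndoC-bH1 beta-cell line (three independent
# preparations; each printed value is the mean of a technical duplicate, so
# both replicate rows carry the same number). Missing amplification is NoCt.
sample	gene	prep	replicate	ct
human_islets	INS	1	1	20.5
human_islets	INS	1	2	20.5
human_islets	INS	2	1	18.9
human_islets	INS	2	2	18.9
human_islets	INS	3	1	20.4
human_islets	INS	3	2	20.4
human_islets	INS-IGF2	1	1	NoCt
human_islets	INS-IGF2	1	2	NoCt
human_islets	INS-IGF2	2	1	33.3
human_islets	INS-IGF2	2	2	33.3
human_islets	INS-IGF2	3	1	34.8
human_islets	INS-IGF2	3	2	34.8
human_islets	IGF2	1	1	32.8
human_islets	IGF2	1	2	32.8
human_islets	IGF2	2	1	32.7
human_islets	IGF2	2	2	32.7
human_islets	IGF2	3	1	31.3
human_islets	IGF2	3	2	31.3
human_islets	GAPDH	1	1	26.9
human_islets	GAPDH	1	2	26.9
human_islets	GAPDH	2	1	27.0
human_islets	GAPDH	2	2	27.0
human_islets	GAPDH	3	1	24.9
human_islets	GAPDH	3	2	24.9
EndoC-bH1	INS	1	1	14.8
EndoC-bH1	INS	1	2	14.8
EndoC-bH1	INS	2	1	14.3
EndoC-bH1	INS	2	2	14.3
EndoC-bH1	INS	3	1	14.4
EndoC-bH1	INS	3	2	14.4
EndoC-bH1	INS-IGF2	1	1	29.9
EndoC-bH1	INS-IGF2	1	2	29.9
EndoC-bH1	INS-IGF2	2	1	30.8
EndoC-bH1	INS-IGF2	2	2	30.8
EndoC-bH1	INS-IGF2	3	1	28.3
EndoC-bH1	INS-IGF2	3	2	28.3
EndoC-bH1	IGF2	1	1	18.3
EndoC-bH1	IGF2	1	2	18.3
EndoC-bH1	IGF2	2	1	19.2
EndoC-bH1	IGF2	2	2	19.2
EndoC-bH1	IGF2	3	1	18.2
EndoC-bH1	IGF2	3	2	18.2
EndoC-bH1	GAPDH	1	1	17.2
EndoC-bH1	GAPDH	1	2	17.2
EndoC-bH1	GAPDH	2	1	18.2
EndoC-bH1	GAPDH	2	2	18.2
EndoC-bH1	GAPDH	3	1	17.1
EndoC-bH1	GAPDH	3	2	17.1
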