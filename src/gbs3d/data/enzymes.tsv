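name	site	cut_offset	methylation_sensitivity
ApeKI	GCWGC	1	partial
PstI	CTGCAG	5	full
NsiI	ATGCAT	5	none
MspI	CCGG	1	none
BglII	AGATCT	1	none
BclI	TGATCA	1	none
BlnI	CCTAGG	1	none
BamHI	GGATCC	1	none
BfaI	CTAG	1	none
BstUI	CGCG	2	none
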