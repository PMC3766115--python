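motif_id	name	sites	genes	genomes_with_site
RF00174	Cobalamin	535	2400	197
RF00059	TPP	564	1800	249
RF00050	FMN	233	432	183
RF00504	Glycine	324	415	145
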