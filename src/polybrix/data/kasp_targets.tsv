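position	marker	target_allele
Ro01:14978562	BBS_SNP45	T
Ro01:14978613	BBS_INDL31	GT
Ro01:14979298	BBS_SNP46	A
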