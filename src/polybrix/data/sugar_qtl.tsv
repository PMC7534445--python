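qtl_name	trait	crop	genome	chrom	start	end	markers
qFRUC.SP-G1	fructose	peach	Ppv1	scaffold_1	10507957	10972280	PC102
SSC-ch13	SSC	apple	Mdv1	Chr13	17977974	18806402	ss475880868-ss475882452
SSC-straw-ch6	SSC	strawberry	Fvv1	LG6	7484789	7911306	AX-89805813-AX-89906546
Sucrose-ch12	sucrose	apple	Mdv1	Chr12	30215039	30750693	ss475880518-ss475880556
qSUCR.CCF-LGVIIa-f	sucrose	strawberry	Fvv1	LG7	20618518	21128712	BFACT044
Sorbitol-ch1a	sorbitol	apple	Mdv1	Chr1	34158601	34656509	ss475876853-ss475876937
Fructose-ch1a	fructose	apple	Mdv1	Chr1	34158601	34656509	ss475876857-ss475876937
Fructose-ch1b	fructose	apple	Mdv1	Chr1	34158601	34656509	ss475883868-ss475876937
Glucose-2012-20wk	glucose	apple	Mdv1	Chr1	34158601	34656509	ss475876868-ss475876937
Glucose-2012-10wk	glucose	apple	Mdv1	Chr1	34158601	34656509	ss475876871-ss475876937
Sorbitol-ch1b	sorbitol	apple	Mdv1	Chr1	34158601	34656509	ss475882286-ss475876937
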