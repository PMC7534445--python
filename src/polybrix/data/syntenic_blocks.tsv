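block_id	genome	chrom	start	end
region1	Ppv1	scaffold_1	10507957	10972280
region1	Fvv1	LG4	18318384	19134134
region1	Mdv1	Chr13	17977974	18806402
region2	Ppv1	scaffold_6	24867717	25235545
region2	Fvv1	LG6	7484789	7911306
region2	Mdv1	Chr12	30215039	30750693
region3	Ppv1	scaffold_2	25475692	25774711
region3	Fvv1	LG7	20618518	21128712
region3	Mdv1	Chr1	34158601	34656509
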