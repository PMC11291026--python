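##fileformat=VCFv4.2
##source=diurnalgwas 0.1.0
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">
##contig=<ID=1>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	S000000	S000001	S000002
1	1000	var0000	A	G	.	PASS	MAF=0.3	GT:DS	0/0:0.0000	1/1:2.0000	0/0:0.0000
1	2000	var0001	A	G	.	PASS	MAF=0.3	GT:DS	0/0:0.0000	0/0:0.0000	0/0:0.0000
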