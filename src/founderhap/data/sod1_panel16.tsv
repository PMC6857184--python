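id	chrom	pos	kind	alleles	mutation_site
rs4817415	21	NA	snp	C,A	0
rs2070422	21	NA	snp	C,T	0
rs1008270	21	NA	snp	A	0
rs9974610	21	NA	snp	A	0
rs2173962	21	NA	snp	T	0
rs202445	21	NA	snp	T	0
rs121912442	21	NA	snp	C,T	1
rs4816405	21	NA	snp	C,G	0
rs2070424	21	NA	snp	A,G	0
rs1041740	21	NA	snp	C,T	0
CA_repeat	21	NA	microsatellite	10,11,12,13	0
rs2833475	21	NA	snp	A,G	0
rs16988427	21	NA	snp	C,T	0
rs2833481	21	NA	snp	C,T	0
rs2070423	21	NA	snp	C,T	0
rs2833483	21	NA	snp	C,T	0
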