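marker	USA	SWE	CHN	IBS
rs4817415	C	C	-	C
rs2070422	T	C	C	C
rs1008270	A	A	-	A
rs9974610	A	A	-	A
rs2173962	T	T	-	T
rs202445	-	-	-	T
rs121912442	T	T	T	T
rs4816405	G	C	C/G	C
rs2070424	G	A	A	A
rs1041740	C	T	C/T	T
rs2833475	G	A	A	A
rs16988427	C	T	C/T	T
rs2833481	C	T	T	T
rs2070423	T	C	C/T	C
rs2833483	C	T	C/T	T
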