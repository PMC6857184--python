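sample	marker_id	allele1	allele2
II:1	rs4817415	C	C
II:1	rs2070422	C	C
II:1	rs1008270	A	A
II:1	rs9974610	A	A
II:1	rs2173962	T	T
II:1	rs202445	T	T
II:1	rs121912442	T	C
II:1	rs4816405	C	C
II:1	rs2070424	A	A
II:1	rs1041740	T	T
II:1	rs2833475	A	A
II:1	rs16988427	T	T
II:1	rs2833481	T	T
II:1	rs2070423	C	C
II:1	rs2833483	T	T
II:5	rs4817415	C	A
II:5	rs2070422	C	C
II:5	rs1008270	A	A
II:5	rs9974610	A	A
II:5	rs2173962	T	T
II:5	rs202445	T	T
II:5	rs121912442	T	C
II:5	rs4816405	C	C
II:5	rs2070424	A	A
II:5	rs1041740	T	T
II:5	rs2833475	A	A
II:5	rs16988427	T	T
II:5	rs2833481	T	T
II:5	rs2070423	C	C
II:5	rs2833483	T	T
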