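chrom	pos	ref	alt	gene	transcript	consequence	maf_1000g_eur	maf_exac	maf_inhouse	cadd_phred	svm_label	clinvar_flag
chr1	100	A	G	G1	G1-T1	missense	0.001	0.001	0.0	25.0	tolerated	0
chr1	200	C	T	G1	G1-T1	missense	0.0	0.0	0.0	30.0	damaging	0
chr1	300	G	A	G1	G1-T1	missense	0.0	0.0	0.0	30.0	damaging	0
chr1	400	T	C	G1	G1-T1	missense	0.0	0.0	0.0	30.0	damaging	0
chr1	800	A	G	G1	G1-T1	frameshift	0.0	0.0	0.0		missing	1
chr2	500	A	T	G2	G2-T1	missense	0.01	0.01	0.0	28.0	damaging	0
chr2	600	G	C	G2	G2-T1	missense	0.002	0.05	0.0	26.0	damaging	0
chr2	700	C	G	G2	G2-T1	synonymous	0.0	0.0	0.0	1.0	missing	0
chr2	900	T	A	G2	G2-T1	stop_gained	0.0	0.0	0.0	35.0	missing	0
chr3	1000	C	T	G3	G3-T1	missense	0.0	0.0	0.0	5.0	tolerated	0
chr3	1100	G	T	G3	G3-T1	inframe_indel	0.0	0.0	0.0		missing	0
chr3	1200	A	C	G3	G3-T1	missense	0.0	0.0	0.0	10.0	damaging	1
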