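##fileformat=VCFv4.2
##contig=<ID=chr1,length=250000000>
##contig=<ID=chr2,length=250000000>
##contig=<ID=chr3,length=250000000>
##INFO=<ID=RD,Number=1,Type=Integer,Description="Read depth at the site">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	S1	S2	S3	S4	S5	S6
chr1	100	.	A	G	.	.	RD=135;MQ=60;QD=15	GT	0/1	0/0	0/0	0/0	0/0	0/0
chr1	200	.	C	T	.	.	RD=10;MQ=60;QD=15	GT	0/1	0/0	0/0	0/0	0/0	0/0
chr1	300	.	G	A	.	.	RD=50;MQ=40;QD=15	GT	0/0	0/1	0/0	0/0	0/0	0/0
chr1	400	.	T	C	.	.	RD=50;MQ=60;QD=2	GT	0/0	0/0	0/1	0/0	0/0	0/0
chr1	800	.	A	G	.	.	RD=90;MQ=58;QD=20	GT	0/0	0/0	0/0	0/1	0/0	0/0
chr2	500	.	A	T	.	.	RD=80;MQ=55;QD=12	GT	0/1	0/1	0/1	0/0	0/0	0/0
chr2	600	.	G	C	.	.	RD=80;MQ=55;QD=12	GT	0/1	0/0	0/0	0/0	0/0	0/0
chr2	700	.	C	G	.	.	RD=80;MQ=55;QD=12	GT	0/0	0/1	0/0	0/0	0/0	0/0
chr2	900	.	T	A	.	.	RD=85;MQ=57;QD=18	GT	0/0	0/0	0/0	0/0	1/1	0/0
chr3	1000	.	C	T	.	.	RD=70;MQ=52;QD=10	GT	0/0	0/0	0/0	0/0	0/0	0/1
chr3	1100	.	G	T	.	.	RD=75;MQ=53;QD=11	GT	0/0	0/1	0/0	0/0	0/0	0/0
chr3	1200	.	A	C	.	.	RD=88;MQ=59;QD=22	GT	0/0	0/0	0/1	0/0	0/0	0/0
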