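sample_id	chromosome	position	ref	alt	depth	vaf	gene	expected_pass
P1	1	1000	C	T	50	0.1		True
P1	1	2000	T	C	50	0.1		True
P1	1	3000	G	A	50	0.1		True
P1	1	4000	A	G	50	0.1		True
P1	1	5000	C	A	50	0.1		False
P1	1	6000	C	G	50	0.1		False
P1	1	7000	T	A	50	0.1		False
P1	1	8000	T	G	50	0.1		False
P1	1	9000	G	T	50	0.1		False
P1	1	10000	G	C	50	0.1		False
P1	1	11000	A	T	50	0.1		False
P1	1	12000	A	C	50	0.1		False
P1	2	13000	C	T	24	0.1		False
P1	2	14000	C	T	25	0.1		True
P1	2	15000	C	T	100	0.1		True
P1	2	16000	C	T	101	0.1		False
P1	3	17000	C	T	50	0.35		True
P1	3	18000	C	T	50	0.351		False
P1	3	19000	C	T	50	0.5		False
P1	3	20000	C	T	50	0.1	DNMT3A	False
P2	4	1000	C	T	50	0.1	TET2	False
P2	4	2000	T	C	50	0.1	ASXL1	False
P2	4	3000	G	A	50	0.1	JAK2	False
P2	4	4000	C	T	50	0.1	TP53	True
P2	4	5000	C	T	50	0.1		True
P2	5	6000	G	A	25	0.35		True
P2	5	7000	A	G	24	0.1		False
P2	5	8000	T	C	50	0.351		False
P2	5	9000	C	G	24	0.1		False
P2	5	10000	G	A	50	0.1	JAK2	False
P2	6	11000	T	C	100	0.35		True
P2	6	12000	C	T	101	0.4		False
P2	6	13000	A	G	60	0.2		True
P2	6	14000	C	A	50	0.1		False
P2	6	15000	T	C	30	0.0		True
P2	7	16000	C	T	40	0.12		True
P2	7	17000	G	A	55	0.33		True
P2	7	18000	T	G	55	0.1		False
P2	7	19000	A	T	55	0.1		False
P2	7	20000	T	C	55	0.34		True
P3	8	1000	C	T	26	0.05		True
P3	8	2000	C	T	99	0.349		True
P3	8	3000	G	C	28	0.1		False
P3	8	4000	A	G	101	0.1		False
P3	9	5000	T	C	25	0.35		True
P3	9	6000	C	T	50	0.36		False
P3	9	7000	G	A	50	0.35		True
P3	9	8000	C	G	24	0.5		False
P3	10	9000	T	C	77	0.2		True
P3	10	10000	A	C	77	0.2		False
P3	10	11000	C	T	77	0.2	DNMT3A	False
P3	10	12000	G	A	77	0.2	ASXL1	False
P3	11	13000	T	C	88	0.1		True
P3	11	14000	C	T	33	0.3		True
P3	11	15000	G	T	33	0.3		False
P4	12	1000	C	T	50	0.1		True
P4	12	2000	T	C	50	0.1		True
P4	12	3000	G	A	24	0.1		False
P4	12	4000	A	G	50	0.36		False
P4	12	5000	C	A	50	0.4		False
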