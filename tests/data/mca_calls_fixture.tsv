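sample_id	chromosome	start	end	copy_type	clonal_fraction	lod_baf_phase	relative_coverage	expected_retained	expected_reasons
C01	1	1	5000000	gain	0.1	19	1.0	False	lod_baf_phase
C02	2	1	1900000	loss	0.1	50	1.0	False	min_size
C03	3	1	6000000	gain	0.2	50	2.3	False	constitutional_duplication
C04	4	1	6000000	gain	0.2	50	2.25	True	.
C05	5	1	100000000	gain	0.3	50	2.6	False	constitutional_duplication
C06	6	1	100000000	gain	0.3	50	2.5	True	.
C07	7	1	30000000	gain	0.3	50	2.6	True	.
C08	8	1	5000000	loss	0.2	50	0.4	False	deletion_coverage
C09	9	1	5000000	loss	0.2	50	0.5	True	.
C10	10	1	2000000	cnloh	0.1	20	1.9	True	.
C11	X	1	120000000	loss	0.3	4.9	1.6	False	lod_baf_phase
C12	X	1	120000000	loss	0.3	5	1.6	True	.
C13	X	1	19000000	cnloh	0.2	6	2.0	True	.
C14	Y	1	10000000	loss	0.3	4	1.4	False	lod_baf_phase
C15	11	1	1500000	loss	0.1	10	0.3	False	min_size;lod_baf_phase;deletion_coverage
C16	12	1	10000000	gain	0.3	30	2.3	False	constitutional_duplication
C17	13	1	10500000	gain	0.3	30	2.3	True	.
C18	14	1	50000000	gain	0.4	30	2.6	False	constitutional_duplication
C19	15	1	49000000	gain	0.4	30	2.6	True	.
C20	1	1	248000000	gain	0.6	30	2.6	False	constitutional_duplication
C21	16	1	80000000	cnloh	0.5	25	2.0	True	.
C22	17	1	3000000	cnloh	0.1	21	2.26	False	constitutional_duplication
C23	18	1	3000000	cnloh	0.1	21	2.2	True	.
C24	19	1	2500000	loss	0.05	19.99	1.8	False	lod_baf_phase
C25	20	1	2500000	loss	0.05	20.01	1.8	True	.
C26	21	1	40000000	loss	0.2	100	1.7	True	.
C27	22	1	45000000	cnloh	0.3	60	2.01	True	.
C28	X	1	110000000	loss	0.2	10	1.8	True	.
C29	Y	1	21000000	loss	0.4	5	1.3	True	.
C30	2	1	1999999	gain	0.1	40	2.0	False	min_size
C31	3	1	2000001	gain	0.1	40	2.0	True	.
C32	4	1	9999999	gain	0.2	40	2.3	False	constitutional_duplication
C33	5	1	60000000	loss	0.3	40	0.49	False	deletion_coverage
C34	6	1	60000000	cnloh	0.2	40	2.51	False	constitutional_duplication
C35	7	1	60000000	cnloh	0.2	40	2.5	True	.
C36	8	1	5000000	gain	0.15	19	2.3	False	lod_baf_phase;constitutional_duplication
C37	9	1	1000000	loss	0.1	4	0.2	False	min_size;lod_baf_phase;deletion_coverage
C38	10	1	25000000	loss	0.25	200	1.5	True	.
C39	11	50000000	135000000	cnloh	0.35	90	2.0	True	.
C40	12	1	133000000	gain	0.55	80	2.56	False	constitutional_duplication
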