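exp_id	res_i	atom_i	res_j	atom_j	shift1_ppm	shift2_ppm	intensity	alt_assignments
CORD_glucose_16	1	CB	2	CD	30.9800	24.0000	0.0582	
CORD_glucose_16	1	CB	4	CD	30.9800	24.6000	0.1276	
CORD_glucose_16	5	C	6	C	171.7200	175.5000	5.5726	
CORD_glucose_16	5	C	7	CG	171.7200	28.8700	0.1085	
CORD_glucose_16	5	C	8	C	171.7200	178.2000	0.2773	
CORD_glucose_16	5	C	9	C	171.7200	174.6700	0.0689	
CORD_glucose_16	5	C	9	CD	171.7200	23.6700	0.5529	26.C-5.C;25.C-5.C
CORD_glucose_16	6	C	7	CG	175.5000	28.8700	0.7112	
CORD_glucose_16	6	C	8	C	175.5000	178.2000	0.4589	
CORD_glucose_16	6	C	9	C	175.5000	174.6700	0.2773	
CORD_glucose_16	6	C	9	CD	175.5000	23.6700	0.2229	
CORD_glucose_16	6	C	10	C	175.5000	173.2400	0.0689	
CORD_glucose_16	6	C	10	CD	175.5000	22.2400	0.5529	
CORD_glucose_16	7	CG	8	C	28.8700	178.2000	0.0405	
CORD_glucose_16	7	CG	10	CD	28.8700	22.2400	0.1144	
CORD_glucose_16	7	CG	17	CG	28.8700	29.1100	0.0657	
CORD_glucose_16	8	C	9	C	178.2000	174.6700	5.5726	
CORD_glucose_16	8	C	9	CD	178.2000	23.6700	0.1204	
CORD_glucose_16	8	C	10	C	178.2000	173.2400	0.4589	
CORD_glucose_16	8	C	10	CD	178.2000	22.2400	0.0391	
CORD_glucose_16	8	C	11	CB	178.2000	31.2200	0.6275	15.C-2.CD;6.C-17.CG
CORD_glucose_16	8	C	12	CD	178.2000	24.2400	0.5529	
CORD_glucose_16	8	C	20	CD	178.2000	22.4800	0.0563	
CORD_glucose_16	9	C	9	CD	174.6700	23.6700	0.2414	
CORD_glucose_16	9	C	10	C	174.6700	173.2400	5.5726	
CORD_glucose_16	9	C	10	CD	174.6700	22.2400	0.1204	
CORD_glucose_16	9	C	11	CB	174.6700	31.2200	0.2108	
CORD_glucose_16	9	C	12	CD	174.6700	24.2400	0.2229	7.CG-30.C
CORD_glucose_16	9	C	13	CD	174.6700	23.1200	0.5529	
CORD_glucose_16	9	C	20	CD	174.6700	22.4800	0.0707	
CORD_glucose_16	9	CD	12	CD	23.6700	24.2400	0.0316	20.C-26.C;20.CD-6.C;18.C-9.CD
CORD_glucose_16	9	CD	13	CD	23.6700	23.1200	0.0375	
CORD_glucose_16	10	C	10	CD	173.2400	22.2400	0.2414	
CORD_glucose_16	10	C	11	CB	173.2400	31.2200	1.5526	
CORD_glucose_16	10	C	12	CD	173.2400	24.2400	0.0391	
CORD_glucose_16	10	C	13	CD	173.2400	23.1200	0.2229	
CORD_glucose_16	10	C	15	C	173.2400	171.9600	0.1021	18.C-23.CD
CORD_glucose_16	10	C	16	C	173.2400	175.7400	0.0651	
CORD_glucose_16	10	C	17	CG	173.2400	29.1100	0.0981	
CORD_glucose_16	10	C	20	CD	173.2400	22.4800	1.9815	
CORD_glucose_16	10	CD	13	CD	22.2400	23.1200	0.0316	20.CD-12.CD;19.CD-10.CD;9.C-6.C
CORD_glucose_16	10	CD	16	C	22.2400	175.7400	0.0712	
CORD_glucose_16	10	CD	17	CG	22.2400	29.1100	0.4276	
CORD_glucose_16	10	CD	20	CD	22.2400	22.4800	0.1309	
CORD_glucose_16	11	CB	12	CD	31.2200	24.2400	0.0582	
CORD_glucose_16	11	CB	17	CG	31.2200	29.1100	0.0524	
CORD_glucose_16	11	CB	19	C	31.2200	174.9100	0.0392	
CORD_glucose_16	11	CB	20	C	31.2200	173.4800	0.0671	
CORD_glucose_16	11	CB	20	CD	31.2200	22.4800	2.1260	
CORD_glucose_16	11	CB	23	CD	31.2200	20.6000	0.1022	
CORD_glucose_16	14	CD	24	CD	24.8400	25.0800	0.1575	
CORD_glucose_16	15	C	16	C	171.9600	175.7400	2.9227	
CORD_glucose_16	15	C	17	CG	171.9600	29.1100	0.0994	8.C-1.CB
CORD_glucose_16	15	C	20	C	171.9600	173.4800	0.0388	
CORD_glucose_16	15	C	20	CD	171.9600	22.4800	0.2163	
CORD_glucose_16	15	C	21	CB	171.9600	31.4600	0.0341	
CORD_glucose_16	15	C	24	CD	171.9600	25.0800	0.0660	16.C-30.C;19.CD-29.C
CORD_glucose_16	16	C	17	CG	175.7400	29.1100	5.1352	
CORD_glucose_16	16	C	18	C	175.7400	178.4400	0.0717	7.CG-24.CD;29.CD-9.C;18.C-2.CD
CORD_glucose_16	16	C	19	C	175.7400	174.9100	0.0403	
CORD_glucose_16	16	C	20	C	175.7400	173.4800	0.0852	
CORD_glucose_16	16	C	20	CD	175.7400	22.4800	1.0142	
CORD_glucose_16	16	C	21	CB	175.7400	31.4600	0.0715	
CORD_glucose_16	17	CG	18	C	29.1100	178.4400	0.0627	
CORD_glucose_16	17	CG	19	C	29.1100	174.9100	0.0540	
CORD_glucose_16	17	CG	20	C	29.1100	173.4800	0.0401	30.C-28.C
CORD_glucose_16	17	CG	20	CD	29.1100	22.4800	2.9299	
CORD_glucose_16	18	C	19	C	178.4400	174.9100	5.5726	
CORD_glucose_16	18	C	19	CD	178.4400	23.9100	0.1204	
CORD_glucose_16	18	C	20	C	178.4400	173.4800	0.4589	
CORD_glucose_16	18	C	20	CD	178.4400	22.4800	0.0391	12.CD-25.C;2.CD-29.C;5.C-13.CD
CORD_glucose_16	18	C	21	CB	178.4400	31.4600	0.6275	
CORD_glucose_16	18	C	22	CD	178.4400	24.4800	0.5529	
CORD_glucose_16	19	C	19	CD	174.9100	23.9100	0.2414	
CORD_glucose_16	19	C	20	C	174.9100	173.4800	5.5726	
CORD_glucose_16	19	C	20	CD	174.9100	22.4800	0.1204	
CORD_glucose_16	19	C	21	CB	174.9100	31.4600	0.2108	
CORD_glucose_16	19	C	22	CD	174.9100	24.4800	0.2229	
CORD_glucose_16	19	C	23	CD	174.9100	20.6000	0.5529	
CORD_glucose_16	19	CD	22	CD	23.9100	24.4800	0.0316	
CORD_glucose_16	19	CD	23	CD	23.9100	20.6000	0.0375	
CORD_glucose_16	20	C	20	CD	173.4800	22.4800	0.2414	
CORD_glucose_16	20	C	21	CB	173.4800	31.4600	1.5526	
CORD_glucose_16	20	C	22	CD	173.4800	24.4800	0.0391	
CORD_glucose_16	20	C	23	CD	173.4800	20.6000	0.2229	19.C-24.CD;23.CD-26.C;20.CD-5.C;27.CG-14.CD
CORD_glucose_16	20	C	24	CD	173.4800	25.0800	0.5529	
CORD_glucose_16	20	CD	23	CD	22.4800	20.6000	0.0316	20.C-16.C;25.C-30.C;17.CG-4.CD;23.CD-9.C
CORD_glucose_16	20	CD	24	CD	22.4800	25.0800	0.0375	
CORD_glucose_16	21	CB	22	CD	31.4600	24.4800	0.0582	
CORD_glucose_16	21	CB	24	CD	31.4600	25.0800	0.1276	
CORD_glucose_16	25	C	26	C	172.2000	175.9800	5.5726	
CORD_glucose_16	25	C	27	CG	172.2000	29.3500	0.1085	
CORD_glucose_16	25	C	28	C	172.2000	175.9200	0.2773	
CORD_glucose_16	25	C	29	C	172.2000	175.1500	0.0689	
CORD_glucose_16	25	C	29	CD	172.2000	24.1500	0.5529	
CORD_glucose_16	26	C	27	CG	175.9800	29.3500	0.7112	
CORD_glucose_16	26	C	28	C	175.9800	175.9200	0.4589	
CORD_glucose_16	26	C	29	C	175.9800	175.1500	0.2773	
CORD_glucose_16	26	C	29	CD	175.9800	24.1500	0.2229	
CORD_glucose_16	26	C	30	C	175.9800	173.7200	0.0689	
CORD_glucose_16	26	C	30	CD	175.9800	22.7200	0.5529	
CORD_glucose_16	27	CG	28	C	29.3500	175.9200	0.0405	
CORD_glucose_16	27	CG	30	CD	29.3500	22.7200	0.1144	
CORD_glucose_16	28	C	29	C	175.9200	175.1500	5.5726	
CORD_glucose_16	28	C	29	CD	175.9200	24.1500	0.1204	
CORD_glucose_16	28	C	30	C	175.9200	173.7200	0.4589	
CORD_glucose_16	28	C	30	CD	175.9200	22.7200	0.0391	
CORD_glucose_16	29	C	29	CD	175.1500	24.1500	0.2414	9.C-14.CD
CORD_glucose_16	29	C	30	C	175.1500	173.7200	5.5726	
CORD_glucose_16	29	C	30	CD	175.1500	22.7200	0.1204	
CORD_glucose_16	30	C	30	CD	173.7200	22.7200	0.2414	
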