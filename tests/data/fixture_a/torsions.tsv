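residue	angle	target_deg	tolerance_deg
1	psi	-45.0000	20.0000
2	phi	-60.0000	20.0000
2	psi	-45.0000	20.0000
3	phi	-60.0000	20.0000
3	psi	-45.0000	20.0000
4	phi	-60.0000	20.0000
4	psi	-45.0000	20.0000
5	phi	-60.0000	20.0000
5	psi	-45.0000	20.0000
6	phi	-60.0000	20.0000
6	psi	-45.0000	20.0000
7	phi	-60.0000	20.0000
7	psi	-45.0000	20.0000
8	phi	-60.0000	20.0000
8	psi	-45.0000	20.0000
9	phi	-60.0000	20.0000
9	psi	-45.0000	20.0000
10	phi	-60.0000	20.0000
10	psi	-45.0000	20.0000
11	phi	-60.0000	20.0000
11	psi	-45.0000	20.0000
12	phi	-60.0000	20.0000
12	psi	-45.0000	20.0000
13	phi	-60.0000	20.0000
13	psi	-45.0000	20.0000
14	phi	100.0000	20.0000
14	psi	125.0000	20.0000
15	phi	100.0000	20.0000
15	psi	125.0000	20.0000
16	phi	100.0000	20.0000
16	psi	125.0000	20.0000
17	phi	100.0000	20.0000
17	psi	125.0000	20.0000
18	phi	-60.0000	20.0000
18	psi	-45.0000	20.0000
19	phi	-60.0000	20.0000
19	psi	-45.0000	20.0000
20	phi	-60.0000	20.0000
20	psi	-45.0000	20.0000
21	phi	-60.0000	20.0000
21	psi	-45.0000	20.0000
22	phi	-60.0000	20.0000
22	psi	-45.0000	20.0000
23	phi	-60.0000	20.0000
23	psi	-45.0000	20.0000
24	phi	-60.0000	20.0000
24	psi	-45.0000	20.0000
25	phi	-60.0000	20.0000
25	psi	-45.0000	20.0000
26	phi	-60.0000	20.0000
26	psi	-45.0000	20.0000
27	phi	-60.0000	20.0000
27	psi	-45.0000	20.0000
28	phi	-60.0000	20.0000
28	psi	-45.0000	20.0000
29	phi	-60.0000	20.0000
29	psi	-45.0000	20.0000
30	phi	-60.0000	20.0000
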