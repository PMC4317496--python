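# Serial-transfer cultures of the lysine-RS replacement experiment.
# Same conventions as table1.tsv.
culture	days	density_e8_per_ml	inoculum	published_n	published_cumul
1	3	1.2	1e8	11.2	11.2
2	7	0.9	5e8	8.5	19.7
3	4	1.6	1e9	8.3	28.0
4	2	1.4	1e9	8.1	36.2
5	6	1.1	1e9	7.8	44.0
6	3	1.6	1e9	8.3	52.3
7	3	1.4	1e9	8.1	60.4
8	2	1.4	1e9	8.1	68.5
9	2	1.3	1e9	8.0	76.6
10	3	1.1	1e9	7.8	84.3
11	2	1.3	1e9	8.0	92.4
12	2	1.1	1e9	7.8	100.1
13	5	1.4	1e9	8.1	108.3
14	2	1.1	1e9	7.8	116.1
15	3	1.0	1e9	7.6	123.7
16	2	1.6	1e9	8.3	132.0
17	2	1.2	1e9	7.9	139.9
18	3	1.3	1e9	8.0	147.9
19	4	1.8	1e9	8.5	156.4
20	3	1.8	1e9	8.5	164.9
21	4	1.6	1e9	8.3	173.3
22	10	1.8	1e9	8.5	181.7
23	10	2.1	1e9	8.7	190.5
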