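# Serial-transfer cultures of the asparagine-RS replacement experiment.
# density in 1e8 cells/ml; inoculum in cells (1e8 and 5e8 for cultures 1-2,
# 1e9 thereafter); published_n and published_cumul are the printed
# one-decimal generation counts kept for cross-checking.
culture	days	density_e8_per_ml	inoculum	published_n	published_cumul
1	3	1.2	1e8	11.2	11.2
2	7	1.2	5e8	8.9	20.1
3	4	1.0	1e9	7.6	27.8
4	2	1.8	1e9	8.5	36.3
5	6	1.7	1e9	8.4	44.7
6	3	2.0	1e9	8.6	53.3
7	3	1.9	1e9	8.6	61.9
8	2	1.8	1e9	8.5	70.4
9	2	1.7	1e9	8.4	78.8
10	3	1.7	1e9	8.4	87.2
11	2	2.0	1e9	8.6	95.8
12	2	1.5	1e9	8.2	104.1
13	5	1.6	1e9	8.3	112.4
14	2	1.7	1e9	8.4	120.8
15	3	1.5	1e9	8.2	129.0
16	2	2.0	1e9	8.6	137.7
17	2	1.5	1e9	8.2	145.9
18	3	1.6	1e9	8.3	154.2
19	4	1.8	1e9	8.5	162.7
20	3	1.9	1e9	8.6	171.3
21	4	1.9	1e9	8.6	179.9
22	10	2.3	1e9	8.8	188.7
23	10	2.4	1e9	8.9	197.6
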