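# Measured thermodynamics of 38 RNA/DNA hybrid duplexes in 100 mM NaCl
# (100 mM NaCl, 10 mM Na2HPO4, 1 mM Na2EDTA, pH 7.0; Tm at Ct = 8 uM total strands).
# Each duplex is the denoted RNA strand (5'->3') with its Watson-Crick complementary DNA.
# Labels sharing a number with suffixes a/b are pairs with identical nearest-neighbor stacks.
# dH, TdS (at 310.15 K) and dG37 in kcal/mol; Tm in deg C.
# dg37_old/tm_old: predictions from the 1 M NaCl parameters mapped through the
# global linear salt corrections; dg37_new/tm_new: predictions from the bundled
# 100 mM NaCl nearest-neighbor set.
label	rna	dh_meas	dh_err	tds_meas	tds_err	dg37_meas	dg37_err	tm_meas	dg37_old	tm_old	dg37_new	tm_new
1	GGUCGC	-42.6	1.5	-36.0	1.3	-6.6	0.3	27.2	-6.0	20.8	-6.5	27.4
2	CGGACC	-55.0	2.3	-48.6	2.1	-6.4	0.4	26.1	-6.1	21.4	-6.4	27.1
3a	GCCGUGAG	-72.5	2.4	-63.4	2.1	-9.1	0.4	41.2	-7.5	32.2	-8.9	41.0
3b	GAGCCGUG	-78.1	2.5	-69.1	2.3	-9.0	0.4	41.5	-7.5	32.2	-8.9	41.0
4a	GUCAGACU	-57.1	1.4	-50.4	1.2	-6.7	0.2	29.7	-5.8	19.2	-6.7	30.1
4b	GACAGUCU	-54.2	2.9	-47.3	2.5	-6.9	0.5	30.1	-5.8	19.2	-6.7	30.1
5	GAACUGCC	-66.7	1.8	-59.4	1.7	-7.3	0.3	33.5	-7.1	30.1	-7.4	33.7
6	GGCAGUUC	-78.2	3.7	-71.0	3.4	-7.2	0.5	33.8	-6.7	27.0	-7.4	34.0
7	GCGAUCGGA	-77.6	2.8	-67.9	2.4	-9.7	0.5	43.5	-8.5	37.3	-9.9	45.2
8	GCCAGUAGG	-74.8	2.3	-65.4	2.0	-9.4	0.4	42.6	-8.5	38.2	-9.7	43.7
9	GUUCAAUACG	-62.9	2.3	-57.0	2.1	-5.9	0.3	27.5	-6.0	23.4	-6.3	29.6
10	AGGAUGACCG	-79.1	1.5	-68.7	1.3	-10.4	0.3	45.9	-9.6	43.4	-10.9	48.0
11	CGCUUGUUAC	-76.9	2.4	-69.9	2.2	-7.0	0.3	33.1	-6.7	27.1	-6.4	30.3
12	GUAACAAGCG	-81.6	2.2	-72.9	1.9	-8.7	0.3	39.2	-7.8	33.5	-8.7	39.5
13	CACUUGUUAC	-73.9	1.6	-68.0	1.5	-5.9	0.2	28.1	-5.8	22.1	-5.7	27.6
14a	AAUCUGGCCA	-57.8	2.7	-48.7	2.3	-9.1	0.5	42.8	-8.8	39.2	-9.1	41.2
14b	AUGGCUCCAA	-64.5	2.6	-55.6	2.2	-8.9	0.4	40.1	-8.8	39.2	-9.1	41.2
15	GGGGAACAAGG	-110.5	2.4	-96.6	2.1	-13.9	0.4	54.3	-12.1	54.3	-14.1	55.6
16	UUCACCUGGUC	-85.1	1.9	-74.8	1.7	-10.3	0.3	45.3	-9.0	38.8	-10.4	45.5
17a	GGCAGGAAUCCG	-100.8	3.0	-86.6	2.6	-14.2	0.5	56.8	-12.1	51.2	-14.2	56.5
17b	GGAAUCAGGCCG	-107.5	4.3	-93.1	3.8	-14.4	0.7	56.3	-12.1	51.2	-14.2	56.5
18a	UAUCUUCCGAAU	-60.7	1.7	-54.0	1.5	-6.7	0.3	30.2	-7.7	31.4	-7.0	32.9
18b	UAUCCUUCGAAU	-57.5	1.2	-50.9	1.1	-6.6	0.2	29.6	-7.7	31.4	-7.0	32.9
19a	AAUGGAUUACAA	-83.1	2.2	-75.3	2.0	-7.8	0.3	36.3	-8.2	33.9	-8.0	36.8
19b	AUUGGAUACAAA	-79.3	3.6	-71.3	3.2	-8.0	0.5	36.2	-8.2	33.9	-8.0	36.8
20	CCUGGAAUCCAA	-85.1	2.4	-74.0	2.1	-11.1	0.4	48.2	-9.9	42.7	-11.6	49.2
21	GGCUCAAUUGAC	-100.4	2.0	-89.7	1.8	-10.7	0.3	45.2	-9.8	42.2	-10.8	46.2
22a	CGGCCUUGAUCC	-104.8	4.0	-92.1	3.5	-12.7	0.6	51.9	-11.0	45.9	-12.2	51.1
22b	CGGAUUCCUGCC	-92.4	2.6	-80.5	2.3	-11.9	0.4	50.3	-11.0	45.9	-12.2	51.1
23	UCCGAAUUAUCU	-81.5	2.8	-73.6	2.6	-7.9	0.4	35.8	-7.7	31.4	-7.0	32.9
24	AGAUAAUUCGGA	-83.5	2.4	-75.8	2.2	-7.7	0.3	35.5	-8.6	35.5	-8.6	38.9
25	GCUUCUCUCUUC	-73.1	1.1	-66.4	1.0	-6.7	0.1	31.5	-7.7	31.9	-6.8	31.9
26	GAAGAGAGAAGC	-84.8	4.1	-72.3	3.5	-12.5	0.7	54.0	-10.5	49.0	-12.6	52.0
27	UCGUUCUUGUCU	-77.8	2.1	-70.0	1.9	-7.8	0.3	36.4	-7.4	30.1	-7.8	36.0
28	AGACAAGAACGA	-95.9	2.1	-84.7	1.8	-11.2	0.3	47.6	-10.0	44.6	-11.5	48.1
29a	GUUAGCGUUACGC	-89.2	3.1	-78.8	2.7	-10.4	0.5	45.0	-10.1	40.4	-11.0	45.9
29b	GCGUUUACGUAGC	-102.6	1.1	-91.1	1.0	-11.5	0.2	47.8	-10.1	40.4	-11.0	45.9
30	UCACGUAGUCGUAU	-113.6	4.4	-101.0	3.9	-12.6	0.7	49.8	-10.2	40.2	-12.6	50.7
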