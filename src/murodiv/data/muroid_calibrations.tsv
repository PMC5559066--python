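node_id	taxon	min_age	max_age	log_stdev	offset
1	Dipodoidea	48.6	62.3	1.928	46.16
2	Rhizomyinae	23	30.03	1.198	22.86
3	Reithrodontomys	1.8	6.89	1.076	1.630
4	Onychomys	4.9	10.28	1.169	4.753
5	Sigmodontini	4.9	14.93	1.408	4.801
6	Holochilus	0.8	1.24	0.140	0.006
7	Reithrodon	3.5		0.180	2.756
8	Necromys	3.5	4.625	0.326	2.915
9	Auliscomys	4	6.8	0.692	3.679
10	Acomys/Deomys	5.3	8.89	1.927	5.258
11	Gerbillinae/Deomyinae	16	23.7	1.251	15.868
12	Murinae	12.1	14.05	0.885	9.767
13	Apodemus	5.3	7.2	0.515	4.871
14	Neotoma	5.3	10.3	1.001	5.113
15	Lemmus	2.6	3.2	0.185	1.860
16	Ondatra	1.86	2.83	0.211	1.156
17	Mesocricetus/Cricetulus	4.9	5.3	0.150	4.049
18	Mastomys	2.6	4.3	0.311	2.000
19	Mus	5.3	7.2	0.515	4.871
20	Rhabdomys	2.6	8.2	0.674	2.270
21	Dasymys	2.6	4.8	0.674	2.270
22	Aethomys	3.6	5.67	0.470	3.138
23	Otomys	2.6	5.3	0.674	2.270
24	Dendromus	5.3	7.2	0.515	4.871
25	Mystromys	3.6	5.3	0.470	3.138
26	Meriones	2.6	8.72	0.674	2.270
27	Myodes	2.6	5.87	0.181	1.857
28	Arvicolinae	4.9	9.0
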