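# Chromosome-level gene counts for the 42 homoeologous chromosome pairs of the
# allopolyploid diatom Fistulifera solaris JPCC DA0580 (draft genome BDSP00000000).
# H/L columns are keyed by the dGC-defined subgenome (Fso_h / Fso_l) of each copy.
# Chr10 carries a dGC flip-over; segment rows A (upstream) and B (downstream of the
# breakpoint) give segment-wise counts with H/L re-keyed by segment dGC polarity.
chromosome	segment	global_gc_h	global_gc_l	predicted_h	predicted_l	homoeologous_h	homoeologous_l	non_homoeologous_h	non_homoeologous_l
Chr1		45.27	45.31	692	649	617	617	75	32
Chr2		45.34	45.58	585	519	463	463	122	56
Chr3		45.93	45.77	595	562	531	531	64	31
Chr4		45.24	45.3	561	547	499	499	62	48
Chr5		44.85	45.04	497	454	421	421	76	33
Chr6		45.82	45.81	452	422	408	408	44	14
Chr7		45.82	45.68	384	345	322	322	62	23
Chr8		45.59	45.65	387	382	354	354	33	28
Chr9		45.75	45.36	364	340	299	299	65	41
Chr10		45.21	44.83	358	364	291	291	67	73
Chr10	A			308	285	256	256	52	29
Chr10	B			79	50	35	35	44	15
Chr11		45.89	45.83	343	314	297	297	46	17
Chr12		45.75	46.12	381	343	320	320	61	23
Chr13		45.17	45.39	356	332	301	301	55	31
Chr14		45.91	45.64	360	332	293	293	67	39
Chr15		45.5	45.51	338	326	303	303	35	23
Chr16		45.81	46.14	307	271	255	255	52	16
Chr17		46.41	45.81	294	288	260	260	34	28
Chr18		45.73	45.48	291	263	242	242	49	21
Chr19		46.22	45.78	310	297	282	282	28	15
Chr20		45.95	45.73	263	234	214	214	49	20
Chr21		45.17	45.4	273	265	252	252	21	13
Chr22		46.02	45.94	247	238	218	218	29	20
Chr23		45.07	45.42	250	231	215	215	35	16
Chr24		45.81	45.82	250	212	199	199	51	13
Chr25		45.38	45.21	216	203	191	191	25	12
Chr26		45.65	44.56	165	130	118	118	47	12
Chr27		46.11	45.32	107	118	96	96	11	22
Chr28		44.58	45.34	119	101	92	92	27	9
Chr29		46.38	45.38	129	114	103	103	26	11
Chr30		45.6	45.45	121	117	102	102	19	15
Chr31		45.36	45.63	89	78	74	74	15	4
Chr32		45.88	45.71	79	73	67	67	12	6
Chr33		44.92	46.05	63	57	54	54	9	3
Chr34		46.24	46.36	54	50	47	47	7	3
Chr35		44.42	44.99	43	40	35	35	8	5
Chr36		46.2	46.16	50	47	42	42	8	5
Chr37		46.48	46.42	45	34	34	34	11	0
Chr38		46.93	45.68	34	37	33	33	1	4
Chr39		45.55	45.8	33	27	27	27	6	0
Chr40		45.58	45.42	25	21	19	19	6	2
Chr41		44.86	44.34	10	16	8	8	2	8
Chr42		46.05	43.6	9	11	9	9	0	2
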