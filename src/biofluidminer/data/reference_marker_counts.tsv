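# Curated per-biofluid marker count summaries from published breast and lung
# cancer literature searches across 14 biofluids.  Integer columns only; every
# percentage is derived at run time.  The breast-cancer breastmilk pair is
# absent because both its positive and negative queries contain the root
# 'breast', so it was excluded from analysis.
disease	biofluid	total_found	known_found	n_significant	known_significant
breast cancer	bile	200	26	58	7
breast cancer	blood	2084	150	196	9
breast cancer	cerebrospinal fluid	116	8	18	0
breast cancer	mucus	63	13	8	3
breast cancer	plasma	1002	88	100	5
breast cancer	saliva	73	9	10	2
breast cancer	semen	35	3	6	0
breast cancer	serum	1327	106	145	6
breast cancer	synovial fluid	21	0	4	0
breast cancer	stool	68	8	7	3
breast cancer	sweat	123	15	28	3
breast cancer	tears	26	2	3	0
breast cancer	urine	310	32	38	3
lung cancer	bile	167	17	25	1
lung cancer	blood	1863	141	152	7
lung cancer	breastmilk	77	15	11	2
lung cancer	cerebrospinal fluid	106	7	11	1
lung cancer	mucus	276	27	73	10
lung cancer	plasma	843	75	65	4
lung cancer	saliva	53	3	7	1
lung cancer	semen	11	2	0	0
lung cancer	serum	1109	100	103	3
lung cancer	synovial fluid	13	2	3	0
lung cancer	stool	45	2	5	0
lung cancer	sweat	44	5	4	0
lung cancer	tears	12	0	1	0
lung cancer	urine	256	30	56	6
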