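# Transcription of the published 2-DE spot/protein assignments for the
# gliadin fraction of T. aestivum cv. Keumkang (pI 6-11 gel, 98 spots).
# Gliadin rows (spot id, predominant protein, minor-component flag) follow
# the published identification tables; BU-* working names are spelled out
# (alpha/gamma) because table headers are ASCII.  Per-spot volumes are not
# published, so each category's published volume total is divided equally
# over that category's predominant spots (synthetic within-category split;
# category sums are exact).  LMW-GS (L*), non-gluten (N*) and unidentified
# (U*) spot ids are synthetic placeholders: only their counts and volume
# totals are published.  Spot 57 is minor in both gliadin tables; its
# predominant protein lies outside them and it is carried as one of the 11
# LMW-GS spots.  Listings are non-unique: a spot may carry minor-component
# listings in addition to its predominant one.
spot_id	volume_norm	protein_id	category	minor_flag
31	1.354516129032258	AKC91211	alpha	false
34	1.354516129032258	AKC91203	alpha	false
35	1.354516129032258	AKB95609	alpha	false
52	0.0	AKB95609	alpha	true
46	1.354516129032258	AKC91236	alpha	false
47	1.354516129032258	AKC91207	alpha	false
62	0.0	AKC91207	alpha	true
50	1.354516129032258	ABQ52124	alpha	false
51	1.354516129032258	ABQ52124	alpha	false
59	0.0	AFX69641	alpha	true
63	1.354516129032258	AKC91229	alpha	false
91	1.354516129032258	AFF27490	alpha	false
19	1.354516129032258	BAM08461	alpha	false
21	1.354516129032258	BAM08459	alpha	false
25	1.354516129032258	BAM08459	alpha	false
26	1.354516129032258	BU-alpha23	alpha	false
39	1.354516129032258	BU-alpha23	alpha	false
27	1.354516129032258	BAM08455	alpha	false
38	1.354516129032258	BU-alpha12	alpha	false
40	1.354516129032258	BU-alpha8	alpha	false
43	0.0	BAM08454	alpha	true
57	0.0	BAS02443	alpha	true
29	1.354516129032258	ACX71610	alpha	false
30	1.354516129032258	BU-alpha4	alpha	false
33	1.354516129032258	BU-alpha4	alpha	false
32	1.354516129032258	AFX69619	alpha	false
44	1.354516129032258	AFX69619	alpha	false
36	1.354516129032258	BU-alpha10	alpha	false
37	1.354516129032258	BU-alpha3	alpha	false
43	1.354516129032258	BU-alpha3	alpha	false
45	1.354516129032258	AFQ13463	alpha	false
53	1.354516129032258	BU-alpha1	alpha	false
54	1.354516129032258	BU-alpha1	alpha	false
58	0.0	ABS72161	alpha	true
92	1.354516129032258	ABD85199	alpha	false
23	1.354516129032258	AFX69625	alpha	false
28	1.354516129032258	AFX69606	alpha	false
24	0.8871428571428571	AGJ50340	gamma	false
41	0.8871428571428571	AGJ50340	gamma	false
64	0.8871428571428571	ACJ03455	gamma	false
66	0.8871428571428571	BU-gamma6	gamma	false
67	0.8871428571428571	ACJ03500	gamma	false
10	0.8871428571428571	BU-gamma5	gamma	false
11	0.8871428571428571	BU-gamma5	gamma	false
13	0.8871428571428571	BU-gamma5	gamma	false
14	0.8871428571428571	BU-gamma5	gamma	false
15	0.8871428571428571	BU-gamma5	gamma	false
16	0.8871428571428571	BU-gamma5	gamma	false
17	0.8871428571428571	BU-gamma5	gamma	false
56	0.8871428571428571	BU-gamma5	gamma	false
57	0.0	BU-gamma5	gamma	true
95	0.8871428571428571	BU-gamma5	gamma	false
96	0.8871428571428571	BU-gamma5	gamma	false
60	0.8871428571428571	BU-gamma7	gamma	false
61	0.8871428571428571	BU-gamma7	gamma	false
93	0.8871428571428571	BU-gamma7	gamma	false
94	0.8871428571428571	BU-gamma7	gamma	false
70	0.8871428571428571	BU-gamma9	gamma	false
52	0.8871428571428571	BU-gamma10	gamma	false
43	0.0	ACI04085	gamma	true
58	0.8871428571428571	BU-gamma2	gamma	false
73	0.8871428571428571	BU-gamma2	gamma	false
48	0.8871428571428571	AAD30440	gamma	false
49	0.8871428571428571	AAD30440	gamma	false
59	0.8871428571428571	BU-gamma4	gamma	false
62	0.8871428571428571	BU-gamma4	gamma	false
65	0.8871428571428571	BU-gamma4	gamma	false
97	0.45	ADF58069	omega	false
57	1.0863636363636362		lmw_gs	false
L01	1.0863636363636362		lmw_gs	false
L02	1.0863636363636362		lmw_gs	false
L03	1.0863636363636362		lmw_gs	false
L04	1.0863636363636362		lmw_gs	false
L05	1.0863636363636362		lmw_gs	false
L06	1.0863636363636362		lmw_gs	false
L07	1.0863636363636362		lmw_gs	false
L08	1.0863636363636362		lmw_gs	false
L09	1.0863636363636362		lmw_gs	false
L10	1.0863636363636362		lmw_gs	false
N01	0.8971428571428571		non_gluten	false
N02	0.8971428571428571		non_gluten	false
N03	0.8971428571428571		non_gluten	false
N04	0.8971428571428571		non_gluten	false
N05	0.8971428571428571		non_gluten	false
N06	0.8971428571428571		non_gluten	false
N07	0.8971428571428571		non_gluten	false
U01	0.7245		unknown	false
U02	0.7245		unknown	false
U03	0.7245		unknown	false
U04	0.7245		unknown	false
U05	0.7245		unknown	false
U06	0.7245		unknown	false
U07	0.7245		unknown	false
U08	0.7245		unknown	false
U09	0.7245		unknown	false
U10	0.7245		unknown	false
U11	0.7245		unknown	false
U12	0.7245		unknown	false
U13	0.7245		unknown	false
U14	0.7245		unknown	false
U15	0.7245		unknown	false
U16	0.7245		unknown	false
U17	0.7245		unknown	false
U18	0.7245		unknown	false
U19	0.7245		unknown	false
U20	0.7245		unknown	false
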