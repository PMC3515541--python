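index	name	abbrev	hemisphere
1	Superior frontal gyrus, dorsolateral	SFGdor_l	left
2	Superior frontal gyrus, dorsolateral	SFGdor_r	right
3	Superior frontal gyrus, orbital	ORBsup_l	left
4	Superior frontal gyrus, orbital	ORBsup_r	right
5	Superior frontal gyrus, medial	SFGmed_l	left
6	Superior frontal gyrus, medial	SFGmed_r	right
7	Superior frontal gyrus, medial orbital	ORBsupmed_l	left
8	Superior frontal gyrus, medial orbital	ORBsupmed_r	right
9	Middle frontal gyrus	MFG_l	left
10	Middle frontal gyrus	MFG_r	right
11	Middle frontal gyrus, orbital	ORBmid_l	left
12	Middle frontal gyrus, orbital	ORBmid_r	right
13	Inferior frontal gyrus, opercular	IFGoperc_l	left
14	Inferior frontal gyrus, opercular	IFGoperc_r	right
15	Inferior frontal gyrus, triangular	IFGtriang_l	left
16	Inferior frontal gyrus, triangular	IFGtriang_r	right
17	Inferior frontal gyrus, orbital	ORBinf_l	left
18	Inferior frontal gyrus, orbital	ORBinf_r	right
19	Gyrus rectus	REC_l	left
20	Gyrus rectus	REC_r	right
21	Anterior cingulate gyrus	ACG_l	left
22	Anterior cingulate gyrus	ACG_r	right
23	Olfactory cortex	OLF_l	left
24	Olfactory cortex	OLF_r	right
25	Superior parietal gyrus	SPL_l	left
26	Superior parietal gyrus	SPL_r	right
27	Paracentral lobule	PCL_l	left
28	Paracentral lobule	PCL_r	right
29	Postcentral gyrus	PoCG_l	left
30	Postcentral gyrus	PoCG_r	right
31	Inferior parietal gyrus	IPL_l	left
32	Inferior parietal gyrus	IPL_r	right
33	Supramarginal gyrus	SMG_l	left
34	Supramarginal gyrus	SMG_r	right
35	Angular gyrus	ANG_l	left
36	Angular gyrus	ANG_r	right
37	Precuneus	PCUN_l	left
38	Precuneus	PCUN_r	right
39	Posterior cingulate gyrus	PCG_l	left
40	Posterior cingulate gyrus	PCG_r	right
41	Precentral gyrus	PreCG_l	left
42	Precentral gyrus	PreCG_r	right
43	Supplementary motor area	SMA_l	left
44	Supplementary motor area	SMA_r	right
45	Median- and para-cingulate gyrus	MCG_l	left
46	Median- and para-cingulate gyrus	MCG_r	right
47	Superior temporal gyrus	STG_l	left
48	Superior temporal gyrus	STG_r	right
49	Superior temporal gyrus, temporal pole	TPOsup_l	left
50	Superior temporal gyrus, temporal pole	TPOsup_r	right
51	Middle temporal gyrus	MTG_l	left
52	Middle temporal gyrus	MTG_r	right
53	Middle temporal gyrus, temporal pole	TPOmid_l	left
54	Middle temporal gyrus, temporal pole	TPOmid_r	right
55	Inferior temporal gyrus	ITG_l	left
56	Inferior temporal gyrus	ITG_r	right
57	Heschl gyrus	HES_l	left
58	Heschl gyrus	HES_r	right
59	Hippocampus	HIP_l	left
60	Hippocampus	HIP_r	right
61	Parahippocampal gyrus	PHG_l	left
62	Parahippocampal gyrus	PHG_r	right
63	Amygdala	AMYG_l	left
64	Amygdala	AMYG_r	right
65	Insula	INS_l	left
66	Insula	INS_r	right
67	Thalamus	THA_l	left
68	Thalamus	THA_r	right
69	Caudate nucleus	CAU_l	left
70	Caudate nucleus	CAU_r	right
71	Lenticular nucleus, putamen	PUT_l	left
72	Lenticular nucleus, putamen	PUT_r	right
73	Lenticular nucleus, pallidum	PAL_l	left
74	Lenticular nucleus, pallidum	PAL_r	right
75	Calcarine fissure and surrounding cortex	CAL_l	left
76	Calcarine fissure and surrounding cortex	CAL_r	right
77	Cuneus	CUN_l	left
78	Cuneus	CUN_r	right
79	Lingual gyrus	LING_l	left
80	Lingual gyrus	LING_r	right
81	Superior occipital gyrus	SOG_l	left
82	Superior occipital gyrus	SOG_r	right
83	Middle occipital gyrus	MOG_l	left
84	Middle occipital gyrus	MOG_r	right
85	Inferior occipital gyrus	IOG_l	left
86	Inferior occipital gyrus	IOG_r	right
87	Fusiform gyrus	FFG_l	left
88	Fusiform gyrus	FFG_r	right
89	Rolandic operculum	ROL_l	left
90	Rolandic operculum	ROL_r	right
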