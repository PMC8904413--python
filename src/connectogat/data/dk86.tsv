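index	name	hemisphere	class
0	lh-bankssts	left	cortical
1	lh-caudalanteriorcingulate	left	cortical
2	lh-caudalmiddlefrontal	left	cortical
3	lh-cuneus	left	cortical
4	lh-entorhinal	left	cortical
5	lh-fusiform	left	cortical
6	lh-inferiorparietal	left	cortical
7	lh-inferiortemporal	left	cortical
8	lh-isthmuscingulate	left	cortical
9	lh-lateraloccipital	left	cortical
10	lh-lateralorbitofrontal	left	cortical
11	lh-lingual	left	cortical
12	lh-medialorbitofrontal	left	cortical
13	lh-middletemporal	left	cortical
14	lh-parahippocampal	left	cortical
15	lh-paracentral	left	cortical
16	lh-parsopercularis	left	cortical
17	lh-parsorbitalis	left	cortical
18	lh-parstriangularis	left	cortical
19	lh-pericalcarine	left	cortical
20	lh-postcentral	left	cortical
21	lh-posteriorcingulate	left	cortical
22	lh-precentral	left	cortical
23	lh-precuneus	left	cortical
24	lh-rostralanteriorcingulate	left	cortical
25	lh-rostralmiddlefrontal	left	cortical
26	lh-superiorfrontal	left	cortical
27	lh-superiorparietal	left	cortical
28	lh-superiortemporal	left	cortical
29	lh-supramarginal	left	cortical
30	lh-frontalpole	left	cortical
31	lh-temporalpole	left	cortical
32	lh-transversetemporal	left	cortical
33	lh-insula	left	cortical
34	rh-bankssts	right	cortical
35	rh-caudalanteriorcingulate	right	cortical
36	rh-caudalmiddlefrontal	right	cortical
37	rh-cuneus	right	cortical
38	rh-entorhinal	right	cortical
39	rh-fusiform	right	cortical
40	rh-inferiorparietal	right	cortical
41	rh-inferiortemporal	right	cortical
42	rh-isthmuscingulate	right	cortical
43	rh-lateraloccipital	right	cortical
44	rh-lateralorbitofrontal	right	cortical
45	rh-lingual	right	cortical
46	rh-medialorbitofrontal	right	cortical
47	rh-middletemporal	right	cortical
48	rh-parahippocampal	right	cortical
49	rh-paracentral	right	cortical
50	rh-parsopercularis	right	cortical
51	rh-parsorbitalis	right	cortical
52	rh-parstriangularis	right	cortical
53	rh-pericalcarine	right	cortical
54	rh-postcentral	right	cortical
55	rh-posteriorcingulate	right	cortical
56	rh-precentral	right	cortical
57	rh-precuneus	right	cortical
58	rh-rostralanteriorcingulate	right	cortical
59	rh-rostralmiddlefrontal	right	cortical
60	rh-superiorfrontal	right	cortical
61	rh-superiorparietal	right	cortical
62	rh-superiortemporal	right	cortical
63	rh-supramarginal	right	cortical
64	rh-frontalpole	right	cortical
65	rh-temporalpole	right	cortical
66	rh-transversetemporal	right	cortical
67	rh-insula	right	cortical
68	Left-Thalamus-Proper	left	subcortical
69	Left-Caudate	left	subcortical
70	Left-Putamen	left	subcortical
71	Left-Pallidum	left	subcortical
72	Left-Hippocampus	left	subcortical
73	Left-Amygdala	left	subcortical
74	Left-Accumbens-area	left	subcortical
75	Left-VentralDC	left	subcortical
76	Left-Cerebellum-Cortex	left	subcortical
77	Right-Thalamus-Proper	right	subcortical
78	Right-Caudate	right	subcortical
79	Right-Putamen	right	subcortical
80	Right-Pallidum	right	subcortical
81	Right-Hippocampus	right	subcortical
82	Right-Amygdala	right	subcortical
83	Right-Accumbens-area	right	subcortical
84	Right-VentralDC	right	subcortical
85	Right-Cerebellum-Cortex	right	subcortical
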