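parcel_id	name	hemisphere	rsn_label
1	ctx-lh-cuneus	L	visual
2	ctx-lh-lateraloccipital	L	visual
3	ctx-lh-lingual	L	visual
4	ctx-lh-pericalcarine	L	visual
5	ctx-lh-fusiform	L	visual
6	ctx-lh-paracentral	L	somatomotor
7	ctx-lh-postcentral	L	somatomotor
8	ctx-lh-precentral	L	somatomotor
9	ctx-lh-transversetemporal	L	somatomotor
10	ctx-lh-superiortemporal	L	somatomotor
11	ctx-lh-superiorparietal	L	dorsal_attention
12	ctx-lh-inferiorparietal	L	dorsal_attention
13	ctx-lh-bankssts	L	dorsal_attention
14	ctx-lh-middletemporal	L	dorsal_attention
15	ctx-lh-insula	L	ventral_attention
16	ctx-lh-supramarginal	L	ventral_attention
17	ctx-lh-caudalanteriorcingulate	L	ventral_attention
18	ctx-lh-entorhinal	L	limbic
19	ctx-lh-temporalpole	L	limbic
20	ctx-lh-caudalmiddlefrontal	L	frontoparietal
21	ctx-lh-rostralmiddlefrontal	L	frontoparietal
22	ctx-lh-parsopercularis	L	frontoparietal
23	ctx-lh-parstriangularis	L	frontoparietal
24	ctx-lh-parsorbitalis	L	frontoparietal
25	ctx-lh-superiorfrontal	L	default_mode
26	ctx-lh-medialorbitofrontal	L	default_mode
27	ctx-lh-lateralorbitofrontal	L	default_mode
28	ctx-lh-rostralanteriorcingulate	L	default_mode
29	ctx-lh-posteriorcingulate	L	default_mode
30	ctx-lh-isthmuscingulate	L	default_mode
31	ctx-lh-precuneus	L	default_mode
32	ctx-lh-inferiortemporal	L	default_mode
33	ctx-lh-parahippocampal	L	default_mode
34	ctx-lh-frontalpole	L	default_mode
35	ctx-rh-cuneus	R	visual
36	ctx-rh-lateraloccipital	R	visual
37	ctx-rh-lingual	R	visual
38	ctx-rh-pericalcarine	R	visual
39	ctx-rh-fusiform	R	visual
40	ctx-rh-paracentral	R	somatomotor
41	ctx-rh-postcentral	R	somatomotor
42	ctx-rh-precentral	R	somatomotor
43	ctx-rh-transversetemporal	R	somatomotor
44	ctx-rh-superiortemporal	R	somatomotor
45	ctx-rh-superiorparietal	R	dorsal_attention
46	ctx-rh-inferiorparietal	R	dorsal_attention
47	ctx-rh-bankssts	R	dorsal_attention
48	ctx-rh-middletemporal	R	dorsal_attention
49	ctx-rh-insula	R	ventral_attention
50	ctx-rh-supramarginal	R	ventral_attention
51	ctx-rh-caudalanteriorcingulate	R	ventral_attention
52	ctx-rh-entorhinal	R	limbic
53	ctx-rh-temporalpole	R	limbic
54	ctx-rh-caudalmiddlefrontal	R	frontoparietal
55	ctx-rh-rostralmiddlefrontal	R	frontoparietal
56	ctx-rh-parsopercularis	R	frontoparietal
57	ctx-rh-parstriangularis	R	frontoparietal
58	ctx-rh-parsorbitalis	R	frontoparietal
59	ctx-rh-superiorfrontal	R	default_mode
60	ctx-rh-medialorbitofrontal	R	default_mode
61	ctx-rh-lateralorbitofrontal	R	default_mode
62	ctx-rh-rostralanteriorcingulate	R	default_mode
63	ctx-rh-posteriorcingulate	R	default_mode
64	ctx-rh-isthmuscingulate	R	default_mode
65	ctx-rh-precuneus	R	default_mode
66	ctx-rh-inferiortemporal	R	default_mode
67	ctx-rh-parahippocampal	R	default_mode
68	ctx-rh-frontalpole	R	default_mode
69	Left-Thalamus	L	ventral_attention
70	Left-Putamen	L	ventral_attention
71	Left-Pallidum	L	ventral_attention
72	Left-Accumbens	L	limbic
73	Left-Caudate	L	frontoparietal
74	Left-Hippocampus	L	default_mode
75	Left-Amygdala	L	default_mode
76	Right-Thalamus	R	ventral_attention
77	Right-Putamen	R	ventral_attention
78	Right-Pallidum	R	ventral_attention
79	Right-Accumbens	R	limbic
80	Right-Caudate	R	frontoparietal
81	Right-Hippocampus	R	default_mode
82	Right-Amygdala	R	default_mode
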