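roi_id	roi_name	network
1	Precentral_L	DMN
2	Precentral_R	DMN
3	Frontal_Sup_L	DMN
4	Frontal_Sup_R	DMN
5	Frontal_Sup_Orb_L	EAN
6	Frontal_Sup_Orb_R	EAN
7	Frontal_Mid_L	EAN
8	Frontal_Mid_R	EAN
9	Frontal_Mid_Orb_L	EAN
10	Frontal_Mid_Orb_R	EAN
11	Frontal_Inf_Oper_L	EAN
12	Frontal_Inf_Oper_R	EAN
13	Frontal_Inf_Tri_L	EAN
14	Frontal_Inf_Tri_R	EAN
15	Frontal_Inf_Orb_L	EAN
16	Frontal_Inf_Orb_R	EAN
17	Rolandic_Oper_L	SMC
18	Rolandic_Oper_R	SMC
19	Supp_Motor_Area_L	SMC
20	Supp_Motor_Area_R	SMC
21	Olfactory_L	SN
22	Olfactory_R	SN
23	Frontal_Sup_Medial_L	DMN
24	Frontal_Sup_Medial_R	DMN
25	Frontal_Med_Orb_L	DMN
26	Frontal_Med_Orb_R	DMN
27	Rectus_L	DMN
28	Rectus_R	DMN
29	Insula_L	SMC
30	Insula_R	SMC
31	Cingulum_Ant_L	DMN
32	Cingulum_Ant_R	DMN
33	Cingulum_Mid_L	SN
34	Cingulum_Mid_R	SN
35	Cingulum_Post_L	DMN
36	Cingulum_Post_R	DMN
37	Hippocampus_L	SN
38	Hippocampus_R	SN
39	ParaHippocampal_L	SN
40	ParaHippocampal_R	SN
41	Amygdala_L	SN
42	Amygdala_R	SN
43	Calcarine_L	VC
44	Calcarine_R	VC
45	Cuneus_L	VC
46	Cuneus_R	VC
47	Lingual_L	VC
48	Lingual_R	VC
49	Occipital_Sup_L	VC
50	Occipital_Sup_R	VC
51	Occipital_Mid_L	VC
52	Occipital_Mid_R	VC
53	Occipital_Inf_L	VC
54	Occipital_Inf_R	VC
55	Fusiform_L	VC
56	Fusiform_R	VC
57	Postcentral_L	SMC
58	Postcentral_R	SMC
59	Parietal_Sup_L	SMC
60	Parietal_Sup_R	SMC
61	Parietal_Inf_L	EAN
62	Parietal_Inf_R	EAN
63	SupraMarginal_L	SMC
64	SupraMarginal_R	SMC
65	Angular_L	EAN
66	Angular_R	EAN
67	Precuneus_L	DMN
68	Precuneus_R	DMN
69	Paracentral_Lobule_L	SMC
70	Paracentral_Lobule_R	SMC
71	Caudate_L	SN
72	Caudate_R	SN
73	Putamen_L	SN
74	Putamen_R	SN
75	Pallidum_L	SN
76	Pallidum_R	SN
77	Thalamus_L	SN
78	Thalamus_R	SN
79	Heschl_L	SMC
80	Heschl_R	SMC
81	Temporal_Sup_L	SMC
82	Temporal_Sup_R	SMC
83	Temporal_Pole_Sup_L	EAN
84	Temporal_Pole_Sup_R	EAN
85	Temporal_Mid_L	DMN
86	Temporal_Mid_R	DMN
87	Temporal_Pole_Mid_L	DMN
88	Temporal_Pole_Mid_R	DMN
89	Temporal_Inf_L	DMN
90	Temporal_Inf_R	DMN
91	Cerebelum_Crus1_L	Cereb
92	Cerebelum_Crus1_R	Cereb
93	Cerebelum_Crus2_L	Cereb
94	Cerebelum_Crus2_R	Cereb
95	Cerebelum_3_L	Cereb
96	Cerebelum_3_R	Cereb
97	Cerebelum_4_5_L	Cereb
98	Cerebelum_4_5_R	Cereb
99	Cerebelum_6_L	Cereb
100	Cerebelum_6_R	Cereb
101	Cerebelum_7b_L	Cereb
102	Cerebelum_7b_R	Cereb
103	Cerebelum_8_L	Cereb
104	Cerebelum_8_R	Cereb
105	Cerebelum_9_L	Cereb
106	Cerebelum_9_R	Cereb
107	Cerebelum_10_L	Cereb
108	Cerebelum_10_R	Cereb
109	Vermis_1_2	Cereb
110	Vermis_3	Cereb
111	Vermis_4_5	Cereb
112	Vermis_6	Cereb
113	Vermis_7	Cereb
114	Vermis_8	Cereb
115	Vermis_9	Cereb
116	Vermis_10	Cereb
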