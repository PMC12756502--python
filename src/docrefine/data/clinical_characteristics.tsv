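Patient ID	Gender	Age	Months since onset	Etiology	Lesion information	CRS-R score (1st)	Diagnosis
1	M	23	5	TBI	Right basal ganglia lesion	7	MCS
2	M	23	6	TBI	DAI lesion and left thalamus and brainstem atrophy	9	MCS
3	F	28	1	TBI	Brainstem atrophy	15	MCS
4	F	31	3	TBI	Left thalamus and brainstem atrophy	11	MCS
5	M	60	7	TBI	Diffuse white matter damage	11	MCS
6	M	58	12	TBI	Bilateral frontal contusion and brainstem hemorrhage	8	MCS
7	M	29	9	TBI	Multi-focal contusion	18	MCS
8	M	41	1	TBI	DAI and subcortical atrophy	11	MCS
9	F	27	10	TBI	Multi-focal contusion and left frontoparietal hemorrhage	12	MCS
10	F	27	10	TBI	DAI lesion	13	MCS
11	M	39	1	HI	Left basal ganglia hemorrhage and brain atrophy	17	MCS
12	M	23	3	HI	Brainstem atrophy	10	MCS
13	F	28	6	Poisoning	Anoxia caused by drug poisoning	9	MCS
14	F	28	9	Poisoning	Anoxia caused by drug poisoning	10	MCS
15	F	29	21	Poisoning	Anoxia caused by drug poisoning	11	MCS
16	M	61	2	HI	Left basal ganglia and left thalamus hemorrhage	11	MCS
17	M	42	3	HI	Brain atrophy	7	MCS
18	M	42	2	HI	Left thalamus hemorrhage	8	MCS
19	M	53	7	HI	Right basal ganglia hemorrhage	11	MCS
20	M	45	2	HIE	Anoxia caused by drug poisoning	9	MCS
21	M	45	9	HI	Brainstem hemorrhage	9	MCS
22	M	32	6	HI	Multi-focal hemorrhagic lesion	11	MCS
23	M	28	2	CPA	n/a	9	MCS
24	M	28	5	CA	n/a	8	MCS
25	M	46	2	CPA	n/a	9	MCS
26	M	51	6	CA	n/a	9	MCS
27	M	45	3	HIE	n/a	10	MCS
28	F	25	3	HIE	n/a	10	MCS
29	M	41	3	HIE	n/a	11	MCS
30	M	36	5	TBI	n/a	10	MCS
31	M	61	9	TBI	Right frontal contusion	6	VS
32	F	46	15	TBI	n/a	7	VS
33	F	58	2	TBI	Left parietal-occipital lesion and brainstem hemorrhage	3	VS
34	F	66	1	TBI	Bilateral frontoparietal lesion	6	VS
35	M	23	10	TBI	Right frontal lesion	7	VS
36	M	46	4	TBI	Right temporal, parietal and occipital lesion	6	VS
37	M	39	5	TBI	Right basal ganglia hemorrhage	7	VS
38	M	34	3	TBI	DAI and brain atrophy	6	VS
39	M	22	3	TBI	Left frontal, temporal and parietal lesions	7	VS
40	M	51	3	TBI	Right frontal, temporal and parietal lesions	7	VS
41	M	45	1	TBI	n/a	6	VS
42	F	68	6	TBI	Brainstem and right basal ganglia lesions	7	VS
43	F	64	1	HI	Left thalamus and basal ganglia hemorrhage	7	VS
44	M	46	2	HIE	Brainstem hemorrhage	6	VS
45	M	52	4	HIE	Brainstem hemorrhage	5	VS
46	M	39	3	HIE	Left basal ganglia hemorrhage	7	VS
47	F	53	3	HIE	Brainstem hemorrhage	5	VS
48	M	49	10	HI	Brainstem lesion	7	VS
49	M	45	3	TBI	Diffuse white matter damage	7	VS
50	F	67	4	HI	Bilateral brain atrophy	6	VS
51	F	40	5	HI	Brainstem hemorrhage	7	VS
52	M	58	6	HI	Right temporal lobe hemorrhage	7	VS
53	F	26	4	HI	Left basal ganglia hemorrhage	6	VS
54	F	69	4	HI	Multi-focal cerebral infarction	6	VS
55	F	60	4	HIE	Anoxia caused by anesthesia	6	VS
56	M	42	6	HI	Right hemisphere and brainstem lesions	7	VS
57	M	36	1	HIE	Multi-focal cerebral infarction	7	VS
58	M	48	4	HIE	Anoxia caused by electric shock	7	VS
59	F	28	5	HIE	n/a	6	VS
60	M	40	4	HI	Brainstem hemorrhage	4	VS
61	F	35	3	HIE	Severe brain atrophy	6	VS
62	F	29	28	Eclampsia	Intraparenchymal hemorrhage and severe brain atrophy	7	VS
63	F	28	3	HIE	Brainstem lesion and brain atrophy	6	VS
64	F	35	3	HIE	Bilateral basal ganglia and thalamus lesions	7	VS
65	F	42	1	CA	Anoxia caused by amniotic fluid embolism	7	VS
66	M	43	2	CA	Cardiac arrest caused by coronary heart diseases	5	VS
67	F	51	6	CPA	n/a	6	VS
68	M	51	3	CPA	n/a	7	VS
69	F	35	2	CPA	Bilateral frontoparietal lesions	7	VS
70	F	38	2	CPA	Basal ganglia and frontal, temporal and parietal lesions	6	VS
71	M	41	2	CPA	Multi-focal cerebral infarction	5	VS
72	F	50	8	CPA	Bilateral basal ganglia lesions and brain atrophy	6	VS
73	F	71	30	CPA	Multi-focal cerebral infarction and brain atrophy	7	VS
74	M	52	2	CA	n/a	7	VS
75	F	50	6	CPA	n/a	5	VS
76	M	45	9	HIE	n/a	5	VS
77	M	33	9	HIE	n/a	5	VS
78	F	73	2	HIE	n/a	7	VS
79	M	62	2	HIE	n/a	3	VS
80	M	30	2	HIE	n/a	6	VS
81	M	18	8	Asphyxia	n/a	6	VS
82	F	71	3	HIE	n/a	9	VS
83	F	57	2	HIE	n/a	5	VS
84	M	26	54	HIE	n/a	6	VS
85	F		2	CPA	n/a	n/a	VS
86	F	79	2	HIE	n/a	6	VS
87	M	33	2	HIE	n/a	5	VS
88	M	71	6	TBI	Right tempo-parietal lesion and DAI	3	VS
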