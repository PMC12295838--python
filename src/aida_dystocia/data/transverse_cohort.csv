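patient_id,mla_deg,aida_class,delivery_outcome,aida_mla,aida_aop,aida_spd,aida_ad,pred_svm,pred_rf,pred_mlp
116,76,2,ICD,RED,GREEN,GREEN,RED,ICD,ICD,NOICD
128,76,2,NOICD,RED,GREEN,GREEN,YELLOW,ICD,ICD,ICD
76,77,2,ICD,RED,GREEN,GREEN,RED,ICD,ICD,ICD
65,82,2,ICD,RED,GREEN,RED,GREEN,ICD,ICD,ICD
110,75,3,ICD,RED,RED,GREEN,RED,ICD,ICD,ICD
12,77,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
50,77,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
7,78,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
9,81,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
63,81,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
10,84,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
24,86,3,NOICD,RED,RED,RED,GREEN,ICD,ICD,ICD
11,86,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
94,88,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
20,88,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
43,88,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
118,88,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
52,88,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
46,90,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
28,90,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
18,75,4,ICD,RED,RED,RED,RED,ICD,ICD,ICD
71,78,4,ICD,RED,RED,RED,RED,ICD,ICD,ICD
85,79,4,ICD,RED,RED,RED,RED,ICD,ICD,ICD
60,79,4,ICD,RED,RED,RED,YELLOW,ICD,ICD,ICD
4,81,4,ICD,RED,RED,RED,YELLOW,ICD,ICD,ICD
83,83,4,ICD,RED,RED,RED,RED,ICD,ICD,ICD
13,84,4,ICD,RED,RED,RED,YELLOW,ICD,ICD,ICD
114,87,4,ICD,RED,RED,RED,RED,ICD,ICD,ICD
78,89,4,ICD,RED,RED,RED,RED,ICD,ICD,ICD
101,71,2,ICD,RED,GREEN,GREEN,RED,ICD,ICD,ICD
8,72,2,ICD,RED,RED,GREEN,GREEN,ICD,ICD,ICD
91,73,2,ICD,RED,GREEN,GREEN,RED,ICD,ICD,ICD
42,70,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
26,71,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
51,72,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
122,70,4,ICD,RED,RED,RED,RED,ICD,ICD,ICD
69,74,4,ICD,RED,RED,RED,YELLOW,ICD,ICD,ICD
84,74,4,ICD,RED,RED,RED,RED,ICD,ICD,ICD
104,60,0,NOICD,GREEN,GREEN,GREEN,GREEN,NOICD,NOICD,NOICD
53,64,1,ICD,RED,GREEN,GREEN,GREEN,ICD,NOICD,ICD
112,67,1,NOICD,RED,GREEN,GREEN,GREEN,NOICD,NOICD,ICD
25,64,2,ICD,RED,GREEN,RED,GREEN,ICD,ICD,ICD
113,66,2,ICD,RED,GREEN,RED,GREEN,NOICD,ICD,NOICD
55,68,2,ICD,RED,RED,GREEN,GREEN,ICD,ICD,ICD
44,61,3,ICD,YELLOW,RED,RED,GREEN,ICD,ICD,ICD
57,61,3,ICD,YELLOW,RED,RED,GREEN,ICD,ICD,ICD
115,64,3,NOICD,RED,RED,GREEN,RED,ICD,NOICD,ICD
33,64,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
77,67,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
100,67,3,NOICD,RED,RED,GREEN,RED,ICD,ICD,ICD
39,67,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
126,68,3,ICD,RED,RED,GREEN,RED,ICD,ICD,ICD
64,68,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
29,68,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
96,69,3,ICD,RED,RED,RED,GREEN,ICD,ICD,ICD
99,69,3,ICD,RED,GREEN,RED,RED,ICD,ICD,ICD
135,69,3,ICD,RED,RED,GREEN,RED,ICD,ICD,NOICD
2,61,4,ICD,YELLOW,RED,RED,YELLOW,ICD,ICD,ICD
74,64,4,ICD,RED,RED,RED,RED,ICD,ICD,ICD
93,65,4,ICD,RED,RED,RED,RED,ICD,ICD,NOICD
102,65,4,ICD,RED,RED,RED,RED,ICD,ICD,ICD
22,66,4,ICD,RED,RED,RED,RED,ICD,ICD,ICD
121,66,4,ICD,RED,RED,RED,RED,ICD,ICD,ICD
117,67,4,ICD,RED,RED,RED,RED,ICD,ICD,ICD
70,68,4,ICD,RED,RED,RED,YELLOW,ICD,ICD,ICD
67,68,4,ICD,RED,RED,RED,RED,ICD,ICD,ICD
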