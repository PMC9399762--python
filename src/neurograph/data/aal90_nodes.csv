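aal_index,name,hemisphere,tissue,lobe
1,Precentral_L,L,cortical,frontal
2,Precentral_R,R,cortical,frontal
3,Frontal_Sup_L,L,cortical,frontal
4,Frontal_Sup_R,R,cortical,frontal
5,Frontal_Sup_Orb_L,L,cortical,frontal
6,Frontal_Sup_Orb_R,R,cortical,frontal
7,Frontal_Mid_L,L,cortical,frontal
8,Frontal_Mid_R,R,cortical,frontal
9,Frontal_Mid_Orb_L,L,cortical,frontal
10,Frontal_Mid_Orb_R,R,cortical,frontal
11,Frontal_Inf_Oper_L,L,cortical,frontal
12,Frontal_Inf_Oper_R,R,cortical,frontal
13,Frontal_Inf_Tri_L,L,cortical,frontal
14,Frontal_Inf_Tri_R,R,cortical,frontal
15,Frontal_Inf_Orb_L,L,cortical,frontal
16,Frontal_Inf_Orb_R,R,cortical,frontal
17,Rolandic_Oper_L,L,cortical,frontal
18,Rolandic_Oper_R,R,cortical,frontal
19,Supp_Motor_Area_L,L,cortical,frontal
20,Supp_Motor_Area_R,R,cortical,frontal
21,Olfactory_L,L,cortical,frontal
22,Olfactory_R,R,cortical,frontal
23,Frontal_Sup_Medial_L,L,cortical,frontal
24,Frontal_Sup_Medial_R,R,cortical,frontal
25,Frontal_Med_Orb_L,L,cortical,frontal
26,Frontal_Med_Orb_R,R,cortical,frontal
27,Rectus_L,L,cortical,frontal
28,Rectus_R,R,cortical,frontal
29,Insula_L,L,cortical,insula
30,Insula_R,R,cortical,insula
31,Cingulum_Ant_L,L,cortical,limbic
32,Cingulum_Ant_R,R,cortical,limbic
33,Cingulum_Mid_L,L,cortical,limbic
34,Cingulum_Mid_R,R,cortical,limbic
35,Cingulum_Post_L,L,cortical,limbic
36,Cingulum_Post_R,R,cortical,limbic
37,Hippocampus_L,L,subcortical,limbic
38,Hippocampus_R,R,subcortical,limbic
39,ParaHippocampal_L,L,cortical,limbic
40,ParaHippocampal_R,R,cortical,limbic
41,Amygdala_L,L,subcortical,limbic
42,Amygdala_R,R,subcortical,limbic
43,Calcarine_L,L,cortical,occipital
44,Calcarine_R,R,cortical,occipital
45,Cuneus_L,L,cortical,occipital
46,Cuneus_R,R,cortical,occipital
47,Lingual_L,L,cortical,occipital
48,Lingual_R,R,cortical,occipital
49,Occipital_Sup_L,L,cortical,occipital
50,Occipital_Sup_R,R,cortical,occipital
51,Occipital_Mid_L,L,cortical,occipital
52,Occipital_Mid_R,R,cortical,occipital
53,Occipital_Inf_L,L,cortical,occipital
54,Occipital_Inf_R,R,cortical,occipital
55,Fusiform_L,L,cortical,occipital
56,Fusiform_R,R,cortical,occipital
57,Postcentral_L,L,cortical,parietal
58,Postcentral_R,R,cortical,parietal
59,Parietal_Sup_L,L,cortical,parietal
60,Parietal_Sup_R,R,cortical,parietal
61,Parietal_Inf_L,L,cortical,parietal
62,Parietal_Inf_R,R,cortical,parietal
63,SupraMarginal_L,L,cortical,parietal
64,SupraMarginal_R,R,cortical,parietal
65,Angular_L,L,cortical,parietal
66,Angular_R,R,cortical,parietal
67,Precuneus_L,L,cortical,parietal
68,Precuneus_R,R,cortical,parietal
69,Paracentral_Lobule_L,L,cortical,frontal
70,Paracentral_Lobule_R,R,cortical,frontal
71,Caudate_L,L,subcortical,subcortical
72,Caudate_R,R,subcortical,subcortical
73,Putamen_L,L,subcortical,subcortical
74,Putamen_R,R,subcortical,subcortical
75,Pallidum_L,L,subcortical,subcortical
76,Pallidum_R,R,subcortical,subcortical
77,Thalamus_L,L,subcortical,subcortical
78,Thalamus_R,R,subcortical,subcortical
79,Heschl_L,L,cortical,temporal
80,Heschl_R,R,cortical,temporal
81,Temporal_Sup_L,L,cortical,temporal
82,Temporal_Sup_R,R,cortical,temporal
83,Temporal_Pole_Sup_L,L,cortical,temporal
84,Temporal_Pole_Sup_R,R,cortical,temporal
85,Temporal_Mid_L,L,cortical,temporal
86,Temporal_Mid_R,R,cortical,temporal
87,Temporal_Pole_Mid_L,L,cortical,temporal
88,Temporal_Pole_Mid_R,R,cortical,temporal
89,Temporal_Inf_L,L,cortical,temporal
90,Temporal_Inf_R,R,cortical,temporal
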