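label_id,abbreviation,full_name,periventricular
1,MCP,Middle cerebellar peduncle,True
2,PCT,Pontine crossing tract,False
3,GCC,Genu of corpus callosum,True
4,BCC,Body of corpus callosum,True
5,SCC,Splenium of corpus callosum,True
6,FX,Fornix,True
7,CST-R,Corticospinal tract right,False
8,CST-L,Cortical spinal tract left,False
9,ML-R,Medial lemniscus right,True
10,ML-L,Medial lemniscus left,True
11,ICP-R,Inferior cerebellar peduncle right,False
12,ICP-L,Inferior cerebellar peduncle left,False
13,SCP-R,Superior cerebellar peduncle right,True
14,SCP-L,Superior cerebellar peduncle left,True
15,CP-R,Cerebral peduncle right,True
16,CP-L,Cerebral peduncle left,True
17,ALIC-R,Anterior limb of internal capsule right,True
18,ALIC-L,Anterior limb of internal capsule left,True
19,PLIC-R,Posterior limb internal capsule right,False
20,PLIC-L,Posterior limb internal capsule left,False
21,RLIC-R,Retrolenticular part of internal capsule right,True
22,RLIC-L,Retrolenticular part of internal capsule left,True
23,ACR-R,Anterior corona radiata right,True
24,ACR-L,Anterior corona radiata left,True
25,SCR-R,Superior corona radiata right,False
26,SCR-L,Superior corona radiata left,False
27,PCR-R,Posterior corona radiata right,True
28,PCR-L,Posterior corona radiata left,True
29,PTR-R,Posterior thalamic radiation right,False
30,PTR-L,Posterior thalamic radiation left,False
31,SS-R,Sagittal stratum right,True
32,SS-L,Sagittal stratum left,True
33,EC-R,External capsule right,True
34,EC-L,External capsule left,True
35,CGC-R,Cingulum right,False
36,CGC-L,Cingulum left,False
37,CGH-R,Cingulum (hippocampus) right,True
38,CGH-L,Cingulum (hippocampus) left,True
39,FX-ST-R,Fornix or stria-terminalis right,True
40,FX-ST-L,Fornix or stria-terminalis left,True
41,SLF-R,Superior longitudinal fasciculus right,False
42,SLF-L,Superior longitudinal fasciculus left,False
43,SFO-R,Superior frontal occipital fasciculus right,False
44,SFO-L,Superior frontal occipital fasciculus left,False
45,UNC-R,Uncinate fasciculus right,False
46,UNC-L,Uncinate fasciculus left,False
47,TAP-R,Tapetum right,True
48,TAP-L,Tapetum left,True
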