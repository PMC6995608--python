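id,rt_min,formula,calculated_mz,exact_mz,delta_ppm,n_peaks,code,linkage,malonyl,identification
1,5.3,C27H29O17,625.14102,625.14233,2.10,5,Q-3[HEX]-7[HEX],none,0,"Quercetin 3,7-di-O-hexoside"
2,5.74,C33H39O21,771.19893,771.20038,1.88,3,Q-3[RHA(1->6)HEX]-7[HEX],1->6,0,Quercetin 3-O-(6''-O-rhamnosyl)hexoside-7-O-hexoside
3,5.85,C27H29O17,625.14102,625.14172,1.12,8,Q-3[HEX(1->2)HEX],1->2,0,Quercetin 3-O-(2''-O-hexosyl)hexoside
4,5.89,C24H21O14,533.09368,533.09454,1.61,2,K-3[HEX+MAL],none,1,Kaempferol 3-O-(6''-O-malonyl)hexoside
5,5.9,C27H29O16,609.14611,609.14636,0.41,6,K-3[HEX]-7[HEX],none,0,"Kaempferol 3,7-di-O-hexoside"
6,5.91,C34H41O21,785.21458,785.21509,0.65,3,I-3[RHA(1->6)HEX]-7[HEX],1->6,0,Isorhamnetin 3-O-(6''-O-rhamnosyl)hexoside-7-O-hexoside
7,5.96,C28H31O17,639.15667,639.15717,0.78,5,I-3[HEX]-7[HEX],none,0,"Isorhamnetin 3,7-di-O-hexoside"
8,5.98,C33H39O21,771.19893,771.20056,2.11,10,Q-3[HEX(1->2)HEX]-7[RHA],1->2,0,Quercetin 3-O-(2''-O-hexosyl)hexoside-7-O-rhamnoside
9,6.0,C26H27O16,595.13046,595.13098,0.87,7,Q-3[PEN(1->2)HEX],1->2,0,Quercetin 3-O-(2''-O-pentosyl)hexoside
10,6.02,C28H31O17,639.15667,639.15784,1.83,10,I-3[HEX(1->2)HEX],1->2,0,Isorhamnetin 3-O-(2''-O-hexosyl)hexoside
11,6.04,C27H29O16,609.14611,609.14642,0.51,10,Q-3[RHA(1->2)HEX],1->2,0,Quercetin 3-O-(2''-O-rhamnosyl)hexoside
12,6.07,C27H29O16,609.14611,609.14697,1.41,7,K-3[HEX(1->2)HEX],1->2,0,Kaempferol 3-O-(2''-O-hexosyl)hexoside
13,6.19,C33H39O20,755.20402,755.20471,0.91,7,K-3[HEX(1->2)HEX]-7[RHA],1->2,0,Kaempferol 3-O-(2''-O-hexosyl)hexoside-7-O-rhamnoside
14,6.22,C28H31O16,623.16176,623.16211,0.56,10,I-3[RHA(1->2)HEX],1->2,0,Isorhamnetin 3-O-(2''-O-rhamnosyl)hexoside isomer 1
15,6.24,C27H29O16,609.14611,609.14679,1.12,5,Q-3[RHA(1->6)HEX],1->6,0,Quercetin 3-O-(6''-O-rhamnosyl)glucoside (Rutin)
16,6.26,C27H29O16,609.14611,609.14716,1.72,9,I-3[PEN(1->2)HEX],1->2,0,Isorhamnetin 3-O-(2''-O-pentosyl)hexoside
17,6.28,C27H29O15,593.15119,593.15161,0.71,7,K-3[RHA(1->2)HEX],1->2,0,Kaempferol 3-O-(2''-O-rhamnosyl)hexoside
18,6.3,C26H27O15,579.13554,579.13678,2.14,7,K-3[PEN(1->2)HEX],1->2,0,Kaempferol 3-O-(2''-O-pentosyl)hexoside
19,6.34,C28H31O16,623.16176,623.16248,1.16,9,I-3[RHA(1->2)HEX],1->2,0,Isorhamnetin 3-O-(2''-O-rhamnosyl)hexoside isomer 2
20,6.39,C21H19O12,463.08820,463.08951,2.83,2,Q-3[HEX],none,0,Quercetin 3-O-galactoside (Hyperoside)
21,6.43,C27H29O16,609.14611,609.14697,1.41,4,I-3[PEN(1->6)HEX],1->6,0,Isorhamnetin 3-O-(6''-O-pentosyl)hexoside
22,6.54,C24H21O15,549.08859,549.08923,1.17,2,Q-3[HEX+MAL],none,1,Quercetin 3-O-(6''-O-malonyl)hexoside
23,6.57,C28H31O16,623.16176,623.16272,1.54,5,I-3[RHA(1->6)HEX],1->6,0,Isorhamnetin 3-O-(6''-O-rhamnosyl)hexoside
24,6.65,C22H21O12,477.10385,477.10477,1.93,2,I-3[HEX],none,0,Isorhamnetin 3-O-hexoside isomer 1
25,6.7,C21H19O11,447.09329,447.09424,2.12,4,K-3[HEX],none,0,Kaempferol 3-O-glucoside (Astragalin)
26,6.78,C22H21O12,477.10385,477.10437,1.09,4,I-3[HEX],none,0,Isorhamnetin 3-O-hexoside isomer 2
27,6.86,C25H23O15,563.10424,563.10486,1.10,2,I-3[HEX+MAL],none,1,Isorhamnetin 3-O-(6''-O-malonyl)hexoside
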