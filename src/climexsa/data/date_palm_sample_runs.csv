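run,DV0,DV1,DV2,DV3,SM0,SM1,SM2,SM3,TTCS,THCS,TTHS,SMWS,HWS,THHS,area_km2
1,1,1,1,1,1,1,1,1,1,1,1,1,1,1,373977
2,1,1,2,2,2,2,2,2,1,1,1,1,1,1,1435284
3,1,2,2,2,3,3,1,1,1,1,2,2,3,3,1190953
4,1,2,2,2,3,3,1,1,2,2,3,3,1,1,427252
5,1,3,1,2,1,3,2,3,3,1,3,2,1,2,1345530
6,1,3,2,3,2,1,3,1,2,3,2,1,3,1,323326
7,1,3,2,3,2,1,3,1,3,1,3,2,1,2,1364426
8,1,3,3,1,3,2,1,2,3,1,3,2,1,2,1235830
9,2,2,2,3,1,2,1,3,3,1,2,3,2,1,1176781
10,2,2,3,1,2,3,2,1,2,3,1,2,1,3,539052
11,2,3,1,3,2,3,1,2,2,1,3,1,2,3,1045823
12,2,3,3,2,1,2,3,1,1,3,2,3,1,2,315978
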