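code,level1,level2,level3
SM0,0.005,0.007,0.01
SM1,0.011,0.013,0.017
SM2,0.5,0.81,1.0
SM3,0.6,0.9,1.0
DV0,10.0,14.0,18.0
DV1,15.0,20.0,26.0
DV2,30.0,39.0,45.0
DV3,40.0,46.0,50.0
TTCS,2.0,4.0,5.0
THCS,-0.05,-0.01,0.0
TTHS,40.0,46.0,50.0
THHS,0.7,0.9,1.0
SMWS,0.6,0.9,1.0
HWS,0.018,0.022,0.029
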