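DV0=14
DV1=20
DV2=39
DV3=46
SM0=0.007
SM1=0.013
SM2=0.81
SM3=0.9
TTCS=4
THCS=-0.01
TTHS=46
THHS=0.9
SMWS=0.9
HWS=0.022
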