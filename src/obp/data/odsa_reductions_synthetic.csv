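model,regimen,dose_low,dose_medium,dose_high,reduction_low,reduction_medium,reduction_high
PATO073,GEM/PAC,0.02,0.1,0.5,5,12,22
PATO044,GEM/PAC,0.02,0.1,0.5,18,35,52
PATO080,GEM/PAC,0.02,0.1,0.5,33,41,58
PATO075,GEM/PAC,0.02,0.1,0.5,36,44,61
PATO068,GEM/PAC,0.02,0.1,0.5,4,9,18
PATO043,GEM/PAC,0.02,0.1,0.5,10,16,26
PATO069,GEM/PAC,0.02,0.1,0.5,7,14,24
PATO082,GEM/PAC,0.02,0.1,0.5,6,15,27
PATO061,GEM/PAC,0.02,0.1,0.5,-3,5,12
PATO071,GEM/PAC,0.02,0.1,0.5,2,8,19
PATO072,GEM/PAC,0.02,0.1,0.5,31,45,57
PATO032,GEM/PAC,0.02,0.1,0.5,22,34,49
PATO035,GEM/PAC,0.02,0.1,0.5,3,10,21
PATO077,GEM/PAC,0.02,0.1,0.5,-5,4,14
PATO062,GEM/PAC,0.02,0.1,0.5,9,17,28
PATO066,GEM/PAC,0.02,0.1,0.5,1,7,16
PATO081,GEM/PAC,0.02,0.1,0.5,38,47,63
PATO083,GEM/PAC,0.02,0.1,0.5,8,15,25
PATO084,GEM/PAC,0.02,0.1,0.5,34,46,60
FNA26,GEM/PAC,0.02,0.1,0.5,5,13,23
FNA27,GEM/PAC,0.02,0.1,0.5,32,43,55
PATO073,FFX,0.02,0.1,0.5,6,11,20
PATO044,FFX,0.02,0.1,0.5,12,18,27
PATO080,FFX,0.02,0.1,0.5,35,48,62
PATO075,FFX,0.02,0.1,0.5,31,42,56
PATO068,FFX,0.02,0.1,0.5,37,49,64
PATO043,FFX,0.02,0.1,0.5,24,36,51
PATO069,FFX,0.02,0.1,0.5,33,44,59
PATO082,FFX,0.02,0.1,0.5,19,32,47
PATO061,FFX,0.02,0.1,0.5,30,40,54
PATO071,FFX,0.02,0.1,0.5,8,16,26
PATO072,FFX,0.02,0.1,0.5,36,45,58
PATO032,FFX,0.02,0.1,0.5,7,13,22
PATO035,FFX,0.02,0.1,0.5,2,9,18
PATO077,FFX,0.02,0.1,0.5,4,12,21
PATO062,FFX,0.02,0.1,0.5,28,39,53
PATO066,FFX,0.02,0.1,0.5,-2,6,15
PATO081,FFX,0.02,0.1,0.5,11,17,28
PATO083,FFX,0.02,0.1,0.5,39,50,66
PATO084,FFX,0.02,0.1,0.5,32,44,57
FNA26,FFX,0.02,0.1,0.5,34,46,61
FNA27,FFX,0.02,0.1,0.5,10,14,24
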