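pdo_id,sma_ck19_ratio,survival_months,event
PATO054,1.82,40.3,False
PATO020,2.61,38.1,False
PATO048,1.45,45.6,False
PATO043,1.21,36.4,False
PATO032,1.58,33.9,False
PATO038,0.52,17.8,True
SYNPDO1,0.78,24.5,True
SYNPDO2,0.61,9.6,True
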