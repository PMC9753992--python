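pdo_id,regimen,ca199_pre,ca199_post,ca199_followup,received_neoadjuvant,survival_months,event,sma_ck19_ratio
PATO073,GA,420,160,150,True,,,
PATO044,GA,510,210,380,True,,,
PATO080,GA+FFX,640,230,410,True,,,
PATO075,GA+FFX,380,140,120,True,,,
PATO068,FFX,290,110,95,True,,,
PATO043,FFX,450,170,150,True,,,
PATO069,FFX,350,120,100,True,,,
PATO082,FFX,275,90,85,True,,,
PATO061,FFX,520,260,240,True,,,
PATO071,FFX,610,280,260,True,,,
PATO072,other,150,230,310,True,,,
PATO032,FFX,12,9,10,True,,,
PATO035,GA,20,18,22,True,,,
PATO077,FFX,8,7,9,True,,,
PATO062,GA,25,21,19,True,,,
PATO066,FFX,15,13,14,True,,,
PATO081,none,480,,200,False,,,
PATO083,none,390,,160,False,,,
PATO084,none,310,,150,False,,,
FNA26,none,820,,95,False,,,
FNA27,none,700,,80,False,,,
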