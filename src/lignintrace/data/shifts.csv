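unit,carbon,shift_ppm,n_carbons,labelable
G,C1,135.0,1,True
G,C2,111.0,1,True
G,C3/4,147.0,2,True
G,C5,115.0,1,True
G,C6,119.0,1,True
S,C1,134.0,1,True
S,C2/6,104.0,2,True
S,C3/5,153.0,2,True
S,C4,138.0,1,True
H,C1,130.0,1,True
H,C2/6,128.0,2,True
H,C3/5,116.0,2,True
H,C4,160.0,1,True
FA,C1,126.0,1,True
FA,C2,111.0,1,True
FA,C3,148.0,1,True
FA,C4,149.0,1,True
FA,C5,116.0,1,True
FA,C6,123.0,1,True
FA,C7,145.0,1,True
FA,C8,117.0,1,True
FA,C9,168.0,1,True
pCA,C4,160.0,1,True
pCA,C9,168.0,1,True
OMe,CH3,56.0,1,False
CARB,C1,105.0,1,False
CARB,C4cr,89.0,1,False
CARB,C4am,84.0,1,False
CARB,C2/3/5,73.0,3,False
CARB,C6cr,65.0,1,False
CARB,C6am,62.0,1,False
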