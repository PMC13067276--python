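unit,site_a,site_b,f1_ppm,f2_ppm,name
G,C2,C1,111.0,135.0,G2/5-1
G,C5,C1,115.0,135.0,G2/5-1
G,C2,C3/4,111.0,147.0,G2/5-3/4
G,C5,C3/4,115.0,147.0,G2/5-3/4
S,C2/6,C3/5,104.0,153.0,S2/6-3/5
S,C2/6,C1,104.0,134.0,S2/6-1
S,C2/6,C4,104.0,138.0,S2/6-4
H,C3/5,C4,116.0,160.0,H3/5-4
H,C2/6,C4,128.0,160.0,H2/6-4
FA,C2,C9,111.0,168.0,FA2/5/8-9
FA,C5,C9,116.0,168.0,FA2/5/8-9
FA,C8,C9,117.0,168.0,FA2/5/8-9
FA,C1,C9,126.0,168.0,FA1/6-9
FA,C6,C9,123.0,168.0,FA1/6-9
FA,C3,C9,148.0,168.0,FA3/4/7-9
FA,C4,C9,149.0,168.0,FA3/4/7-9
FA,C7,C9,145.0,168.0,FA3/4/7-9
pCA,C4,C9,160.0,168.0,pCA4-9
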