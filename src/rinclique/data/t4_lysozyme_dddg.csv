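mutation,dddg_observed_kcal,dddg_maestro_kcal,ca_distance
S117I/N132I,-1.5,1.12,5.95
K16E/K135E,-0.2,0.40,33.69
K16E/R154E,-0.2,0.69,35.33
A41V/V131A,-0.11,-0.21,39.20
N116D/R119M,-0.1,-0.60,5.09
D89A/R96H,-0.1,0.87,8.35
R119E/K135E,-0.06,0.07,15.06
K16E/R119E,-0.06,0.32,39.63
E128A/V131A,-0.01,-1.11,5.38
K135E/K147E,0.2,-0.04,11.58
K85A/R96H,0.2,-0.40,10.73
S38D/N144D,0.3,0.14,29.07
A98V/T152S,2.7,1.84,6.35
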