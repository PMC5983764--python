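site_i,site_j,wt,k16e,r154e,k16e_r154e,s117i,n132i,s117i_n132i
116,119,0,0,0,0,0,0,0
117,132,0.48,0.45,0.28,0.56,0.60,0.39,0.52
119,135,0,0,0,0,0,0,0
128,131,0,0,0.01,0,0,0,0
135,147,0,0,0,0,0,0,0
16,119,0,0,0,0,0,0,0
16,135,0,0,0,0,0,0,0
16,154,0,0,0,0,0,0,0
38,144,0,0,0,0,0,0,0
41,131,0,0,0,0,0,0,0
85,96,0.07,0.05,0.05,0.05,0.12,0.11,0
89,96,0,0,0,0,0,0,0
98,152,0.43,0.40,0.24,0.03,0.02,0.56,0.12
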