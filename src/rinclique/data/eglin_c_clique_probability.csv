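site_i,site_j,distance,dddg_kj,dddg_err_kj,p_ab
18,27,14.2,-0.12,0.20,0
18,54,8.2,-0.95,0.19,0.11
34,58,17.2,-0.38,0.13,0
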