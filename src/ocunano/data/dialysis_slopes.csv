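label,role,slope_mag,slope_sd,r2
Control,control,0.44,0.04,0.97
QA-Ch,formulation,0.23,0.03,0.94
NP QA-Ch,formulation,0.37,0.03,0.98
QA-Ch-S-pro,formulation,0.28,0.04,0.93
NP QA-Ch-S-pro,formulation,0.37,0.03,0.98
SB-Ch,formulation,0.29,0.06,0.90
NP SB-Ch,formulation,0.41,0.06,0.93
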