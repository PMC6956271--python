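label,size_nm,pdi,zeta_mV,ee_pct
QA-Ch,294.3,0.4,9.1,18.4
QA-Ch-S-pro,340.7,0.3,9.5,18.3
SB-Ch,390.6,0.2,-3.5,15.6
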