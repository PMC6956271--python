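label,slope,slope_sd,cum_release_5h,cum_release_sd
Ch NP+TSOH,3.34,0.32,59.50,0.90
QA-Ch NP+TSOH,3.14,0.39,52.23,1.07
QA-Ch-S-pro NP+TSOH,3.64,3.12,65.93,5.70
SB-Ch NP+TSOH,2.43,0.21,37.00,3.82
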