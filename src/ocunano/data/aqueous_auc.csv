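label,auc_ug_h_ml,auc_sd,n
Control,0.62,0.1,6
TSOH,2.32,0.26,6
Ch NP+TSOH,2.23,0.39,6
QA-Ch NP+TSOH,3.30,0.52,6
SB-Ch NP+TSOH,3.34,0.53,6
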