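category,weight
DM_SEVERE,0.60
DM_MILD,0.17
CHF,0.43
COPD,0.38
CKD_SEVERE,0.50
CKD_MILD,0.13
CANCER,0.95
DEPRESSION,0.29
ARTHRITIS,0.21
OBESITY,0.12
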