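code,category
E10,DM_SEVERE
E10.2,DM_SEVERE
E11,DM_MILD
E11.9,DM_MILD
I50,CHF
I50.3,CHF
J44,COPD
J44.1,COPD
N18.5,CKD_SEVERE
N18.3,CKD_MILD
C50,CANCER
C61,CANCER
F32,DEPRESSION
F33,DEPRESSION
M06,ARTHRITIS
M15,ARTHRITIS
E66,OBESITY
E66.0,OBESITY
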