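dominant,subordinate
DM_SEVERE,DM_MILD
CKD_SEVERE,CKD_MILD
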