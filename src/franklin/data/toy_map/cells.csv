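age_min,age_max,sex,weight
65,74,F,0.33
65,74,M,0.35
75,84,F,0.45
75,84,M,0.49
85,120,F,0.62
85,120,M,0.68
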