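age_lo,age_hi,sex,rate_lo,rate_hi
0,14,male,0,0.18
0,14,female,0,0.07
15,24,male,0.12,0.18
15,24,female,0.06,0.07
25,34,male,0.06,0.12
25,34,female,0.05,0.06
35,44,male,0.03,0.06
35,44,female,0.03,0.05
45,54,male,0.02,0.03
45,54,female,0.03,0.04
55,64,male,0.01,0.02
55,64,female,0.02,0.04
65,,male,0,0.01
65,,female,0,0.02
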