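code,sex,age,moca,dur_deafness_left,dur_deafness_right,dur_ci_use_left,dur_ci_use_right,cnc_score
S1,M,30,28,,1,,12,82
S2,F,32,28,2,20,30,12,94
S3,M,35,25,12,8,13,17,90
S4,M,49,24,,1,,21,36
S5,F,54,30,1,0,14,15,92
S6,F,58,30,1,5,14,10,92
S7,F,60,30,,33,,10,76
S8,F,63,29,10,11,13,12,68
S9,F,64,28,5,0,11,16,90
S10,F,69,28,12,13,12,11,90
S11,F,71,28,2,1,16,17,99
S12,F,76,29,0,4,22,17,64
S13,M,82,28,1,50,19,11,60
S14,M,82,27,3,7,19,13,96
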