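subject_id,group,gender,age_years,lesion_side,time_since_stroke_days,fma_pre,fma_post
S002,ER,M,60,R,24,28,33
S005,SOC,F,51,R,31,19,28
S007,SOC,F,57,L,26,23,33
S008,ER,M,74,L,21,20,22
S009,SOC,F,64,R,27,24,33
S012,SOC,F,57,R,31,15,23
S013,ER,F,55,L,16,32,33
S015,SOC,M,72,R,32,31,31
S016,ER,M,39,R,36,13,25
S017,SOC,F,45,R,26,26,32
S018,ER,M,54,R,38,22,25
S020,SOC,F,69,R,18,26,28
S021,ER,M,65,R,20,31,34
S022,ER,F,53,L,29,23,27
S023,SOC,M,51,L,27,32,34
S024,SOC,M,73,L,38,24,29
S025,SOC,M,60,L,36,23,23
S026,ER,M,67,L,14,23,25
S028,SOC,F,49,L,28,23,23
S029,ER,F,67,L,38,21,25
S030,SOC,M,58,R,39,27,27
S031,SOC,M,63,L,31,21,26
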