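stratum,rank,term,a,retained
F,1,NAUSEA,2,False
F,2,ANAEMIA,1,False
F,3,FATIGUE,1,False
F,4,MYSTERY SYNDROME,1,False
M,1,DEATH,1,False
M,2,DIARRHOEA,1,False
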