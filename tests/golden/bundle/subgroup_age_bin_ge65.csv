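level,soc,term,a,b,c,d,ror,ror_ci_low,ror_ci_high,prr,chi2,ebgm,eb05,ic,ic025,flag_ror,flag_prr,flag_bcpnn,flag_mgps,retained
PT,Gastrointestinal disorders,NAUSEA,1,1,0,0,,,,,,0.999995,0.998496,0.192645,-1.85163,False,False,False,False,False
PT,General disorders and administration site conditions,DEATH,1,1,0,0,,,,,,0.999995,0.998496,0.192645,-1.85163,False,False,False,False,False
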