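level,soc,term,a,b,c,d,ror,ror_ci_low,ror_ci_high,prr,chi2,ebgm,eb05,ic,ic025,flag_ror,flag_prr,flag_bcpnn,flag_mgps,retained
PT,Blood and lymphatic system disorders,ANAEMIA,1,4,0,0,,,,,,0.999981,0.978414,-0.153474,-2.54082,False,False,False,False,False
PT,Gastrointestinal disorders,NAUSEA,2,3,0,0,,,,,,0.999975,0.978416,0.0807313,-1.66955,False,False,False,False,False
PT,General disorders and administration site conditions,FATIGUE,1,4,0,0,,,,,,0.999981,0.978414,-0.153474,-2.54082,False,False,False,False,False
PT,UNMAPPED,MYSTERY SYNDROME,1,4,0,0,,,,,,0.999981,0.978414,-0.153474,-2.54082,False,False,False,False,False
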