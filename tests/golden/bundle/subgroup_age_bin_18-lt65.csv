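level,soc,term,a,b,c,d,ror,ror_ci_low,ror_ci_high,prr,chi2,ebgm,eb05,ic,ic025,flag_ror,flag_prr,flag_bcpnn,flag_mgps,retained
PT,Blood and lymphatic system disorders,ANAEMIA,1,2,1,6,3,0.122205,73.6467,2.33333,0.47619,1.66716,1.65081,0.125531,-2.48634,False,False,False,False,False
PT,Gastrointestinal disorders,DIARRHOEA,1,2,0,7,,,,,,1.66719,1.65084,0.36257,-2.50362,False,False,False,False,False
PT,Gastrointestinal disorders,NAUSEA,1,2,2,5,1.25,0.068289,22.8807,1.16667,0.0226757,1.66713,1.65078,-0.0780025,-2.54782,False,False,False,False,False
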