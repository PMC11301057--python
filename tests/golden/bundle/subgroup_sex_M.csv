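level,soc,term,a,b,c,d,ror,ror_ci_low,ror_ci_high,prr,chi2,ebgm,eb05,ic,ic025,flag_ror,flag_prr,flag_bcpnn,flag_mgps,retained
PT,Gastrointestinal disorders,DIARRHOEA,1,1,0,7,,,,,,2.23793,2.20094,0.467652,-2.48547,False,False,False,True,False
PT,General disorders and administration site conditions,DEATH,1,1,2,5,2.5,0.0998269,62.6084,1.75,0.321429,2.2377,2.20071,0.0796594,-2.49039,False,False,False,True,False
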