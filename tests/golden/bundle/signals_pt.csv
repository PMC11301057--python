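level,soc,term,a,b,c,d,ror,ror_ci_low,ror_ci_high,prr,chi2,ebgm,eb05,ic,ic025,flag_ror,flag_prr,flag_bcpnn,flag_mgps,retained
PT,Blood and lymphatic system disorders,ANAEMIA,1,6,1,8,1.33333,0.0686033,25.9139,1.28571,0.0362812,1.06696,1.04778,-0.127756,-2.67568,False,False,False,False,False
PT,Gastrointestinal disorders,NAUSEA,2,5,3,6,0.8,0.0934605,6.84781,0.857143,0.0415584,1.06691,1.04773,-0.167945,-2.09975,False,False,False,False,False
PT,Gastrointestinal disorders,DIARRHOEA,1,6,0,9,,,,,,1.06704,1.04784,0.159941,-2.64731,False,False,False,False,False
PT,General disorders and administration site conditions,DEATH,1,6,2,7,0.583333,0.0417707,8.14633,0.642857,0.1628,1.0669,1.04772,-0.367509,-2.77244,False,False,False,False,False
PT,General disorders and administration site conditions,FATIGUE,1,6,1,8,1.33333,0.0686033,25.9139,1.28571,0.0362812,1.06696,1.04778,-0.127756,-2.67568,False,False,False,False,False
PT,UNMAPPED,MYSTERY SYNDROME,1,6,1,8,1.33333,0.0686033,25.9139,1.28571,0.0362812,1.06696,1.04778,-0.127756,-2.67568,False,False,False,False,False
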