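level,soc,term,a,b,c,d,ror,ror_ci_low,ror_ci_high,prr,chi2,ebgm,eb05,ic,ic025,flag_ror,flag_prr,flag_bcpnn,flag_mgps,retained
SOC,Blood and lymphatic system disorders,Blood and lymphatic system disorders,1,6,1,8,1.33333,0.0686033,25.9139,1.28571,0.0362812,1,0.998501,-0.127756,-2.67568,False,False,False,False,False
SOC,Gastrointestinal disorders,Gastrointestinal disorders,3,4,4,5,0.9375,0.127845,6.87478,0.964286,0.00403124,1,0.998501,-0.0567548,-1.70148,False,False,False,False,False
SOC,General disorders and administration site conditions,General disorders and administration site conditions,2,5,3,6,0.8,0.0934605,6.84781,0.857143,0.0415584,0.999999,0.9985,-0.167945,-2.09975,False,False,False,False,False
SOC,UNMAPPED,UNMAPPED,1,6,1,8,1.33333,0.0686033,25.9139,1.28571,0.0362812,1,0.998501,-0.127756,-2.67568,False,False,False,False,False
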