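stratum,rank,term,a,retained
18-<65,1,ANAEMIA,1,False
18-<65,2,DIARRHOEA,1,False
18-<65,3,NAUSEA,1,False
>=65,1,DEATH,1,False
>=65,2,NAUSEA,1,False
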