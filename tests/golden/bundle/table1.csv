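section,category,count,pct
sex,Female,3,60
sex,Male,2,40
sex,Missing,0,0
age,<18,0,0
age,18-<65,2,40
age,>=65,2,40
age,missing,1,20
outcome,Death,2,40
outcome,Hospitalization - Initial or Prolonged,2,40
outcome,Other Serious,2,40
outcome,Missing,0,0
indication,COLON CANCER,3,60
indication,COLORECTAL CANCER METASTATIC,1,20
indication,RECTAL CANCER,1,20
reporter,Consumer,2,40
reporter,Physician,2,40
reporter,Pharmacist,1,20
country,US,4,80
country,JP,1,20
year,2020,4,80
year,2021,1,20
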