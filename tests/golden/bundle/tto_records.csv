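primaryid,start_dt,event_dt,days,status
1002,20200101,20200214,44,included
1012,20200301,20200101,,excluded_event_before_start
1031,20200115,202003,,excluded_partial_date
1041,20200401,,,excluded_missing
1101,20210601,20210611,10,included
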