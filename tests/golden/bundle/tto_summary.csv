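metric,value
n_included,2
median_days,27
q1_days,18.5
q3_days,35.5
bin_0-30_count,1
bin_0-30_pct,50.0
bin_31-60_count,1
bin_31-60_pct,50.0
bin_61-90_count,0
bin_61-90_pct,0.0
bin_91-180_count,0
bin_91-180_pct,0.0
bin_181-365_count,0
bin_181-365_pct,0.0
bin_>365_count,0
bin_>365_pct,0.0
excluded_missing,1
excluded_partial_date,1
excluded_event_before_start,1
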