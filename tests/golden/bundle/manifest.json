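{
  "config": {
    "age_bins": [
      18.0,
      65.0
    ],
    "drug_terms": [
      "TRIFLURIDINE/TIPIRACIL",
      "TAS102",
      "FTD/TPI",
      "LONSURF"
    ],
    "log_level": "INFO",
    "role_filter": [
      "PS"
    ],
    "screen": {
      "chi2_threshold": 4.0,
      "eb05_threshold": 2.0,
      "ic025_threshold": 0.0,
      "mgps_n_jitter": 4,
      "mgps_seed": 0,
      "mgps_tol": 1e-08,
      "min_cases": 3,
      "prr_threshold": 2.0,
      "retention": "all",
      "ror_ci_low": 1.0,
      "yates": false
    },
    "subgroup_min_cohort": 2,
    "subgroup_top_k": 5,
    "subgroups": [
      "sex",
      "age_bin"
    ],
    "top_countries": 5,
    "top_indications": 7
  },
  "counts": {
    "background": 7,
    "cohort": 5,
    "deduplicated": 12,
    "duplicates_removed": 2,
    "event_pairs_pt": 16,
    "event_pairs_soc": 16,
    "reports_read": 14,
    "retained_pt": 0,
    "retained_soc": 0,
    "rows": {
      "DEMO": 14,
      "DRUG": 15,
      "INDI": 7,
      "OUTC": 10,
      "REAC": 19,
      "RPSR": 4,
      "THER": 8
    },
    "subgroup_age_bin_cohort_sizes": {
      "18-<65": 2,
      ">=65": 2,
      "missing": 1
    },
    "subgroup_sex_cohort_sizes": {
      "F": 3,
      "M": 2,
      "missing": 0
    },
    "terms_pt": 6,
    "terms_soc": 4,
    "tto": {
      "excluded_event_before_start": 1,
      "excluded_missing": 1,
      "excluded_partial_date": 1,
      "included": 2
    },
    "unmapped_pts": {
      "MYSTERY SYNDROME": 2
    }
  },
  "notices": [
    "stratum 'missing' excluded: 0 cohort reports < floor 2",
    "stratum 'missing' excluded: 1 cohort reports < floor 2"
  ],
  "version": "0.1.0"
}
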