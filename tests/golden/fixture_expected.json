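{
  "cohort_primaryids": [
    "1002",
    "1012",
    "1031",
    "1041",
    "1101"
  ],
  "survivors": {
    "100": "1002",
    "101": "1012",
    "102": "1021",
    "103": "1031",
    "104": "1041",
    "105": "1051",
    "106": "1061",
    "107": "1071",
    "108": "1081",
    "109": "1091",
    "110": "1101",
    "111": "1111"
  },
  "tables_pt": {
    "ANAEMIA": [
      1,
      6,
      1,
      8
    ],
    "DEATH": [
      1,
      6,
      2,
      7
    ],
    "DIARRHOEA": [
      1,
      6,
      0,
      9
    ],
    "FATIGUE": [
      1,
      6,
      1,
      8
    ],
    "MYSTERY SYNDROME": [
      1,
      6,
      1,
      8
    ],
    "NAUSEA": [
      2,
      5,
      3,
      6
    ]
  },
  "tto_statuses": {
    "1002": {
      "days": 44,
      "status": "included"
    },
    "1012": {
      "days": null,
      "status": "excluded_event_before_start"
    },
    "1031": {
      "days": null,
      "status": "excluded_partial_date"
    },
    "1041": {
      "days": null,
      "status": "excluded_missing"
    },
    "1101": {
      "days": 10,
      "status": "included"
    }
  }
}
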