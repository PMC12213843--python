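{
  "description": "Published diagnostic-performance and outcome counts from a 60,193-pregnancy low-risk NIPT screening cohort (2019-2023, single centre). Stored verbatim as printed; derived metrics are always recomputed from the counts.",
  "cohort": {
    "n_low_risk": 60193,
    "n_positive": 598,
    "n_amniocentesis": 572,
    "n_confirmed_by_amnio": 319,
    "n_refused_diagnosis": 26,
    "n_postnatal_tested": 16,
    "second_draw_rate_pct": 0.67
  },
  "performance": {
    "T21":  {"positive": 41,  "tp": 35,  "fp": 5,   "tn": 60157, "fn": 0, "printed": {"sensitivity": 100.00, "specificity": 99.99, "ppv": 87.50, "npv": 100.00, "fpr": 0.01, "fnr": 0.00}},
    "T18":  {"positive": 10,  "tp": 6,   "fp": 4,   "tn": 60187, "fn": 0, "printed": {"sensitivity": 100.00, "specificity": 99.99, "ppv": 60.00, "npv": 100.00, "fpr": 0.01, "fnr": 0.00}},
    "T13":  {"positive": 24,  "tp": 8,   "fp": 15,  "tn": 60184, "fn": 0, "printed": {"sensitivity": 100.00, "specificity": 99.98, "ppv": 34.78, "npv": 100.00, "fpr": 0.02, "fnr": 0.00}},
    "SCAs": {"positive": 334, "tp": 194, "fp": 135, "tn": 59994, "fn": 0, "printed": {"sensitivity": 100.00, "specificity": 99.78, "ppv": 58.97, "npv": 100.00, "fpr": 0.22, "fnr": 0.00}},
    "XO":   {"positive": 150, "tp": 53,  "fp": 97,  "tn": 60140, "fn": 0, "printed": {"sensitivity": 100.00, "specificity": 99.84, "ppv": 35.33, "npv": 100.00, "fpr": 0.16, "fnr": 0.00}},
    "XXX":  {"positive": 55,  "tp": 35,  "fp": 19,  "tn": 60157, "fn": 0, "printed": {"sensitivity": 100.00, "specificity": 99.97, "ppv": 64.81, "npv": 100.00, "fpr": 0.03, "fnr": 0.00}},
    "XXY":  {"positive": 77,  "tp": 63,  "fp": 10,  "tn": 60126, "fn": 0, "printed": {"sensitivity": 100.00, "specificity": 99.98, "ppv": 86.30, "npv": 100.00, "fpr": 0.02, "fnr": 0.00}},
    "XYY":  {"positive": 52,  "tp": 43,  "fp": 9,   "tn": 60150, "fn": 0, "printed": {"sensitivity": 100.00, "specificity": 99.99, "ppv": 82.69, "npv": 100.00, "fpr": 0.01, "fnr": 0.00}},
    "RAAs": {"positive": 122, "tp": 39,  "fp": 81,  "tn": 60152, "fn": 0, "printed": {"sensitivity": 100.00, "specificity": 99.87, "ppv": 32.50, "npv": 100.00, "fpr": 0.13, "fnr": 0.00}},
    "CNVs": {"positive": 67,  "tp": 46,  "fp": 20,  "tn": 60144, "fn": 2, "printed": {"sensitivity": 95.83,  "specificity": 99.97, "ppv": 69.70, "npv": 100.00, "fpr": 0.03, "fnr": 9.09}},
    "dup":  {"positive": 39,  "tp": 26,  "fp": 13,  "tn": 60167, "fn": 0, "printed": {"sensitivity": 100.00, "specificity": 99.98, "ppv": 66.67, "npv": 100.00, "fpr": 0.02, "fnr": 0.00}},
    "del":  {"positive": 28,  "tp": 20,  "fp": 7,   "tn": 60170, "fn": 2, "printed": {"sensitivity": 91.91,  "specificity": 99.99, "ppv": 74.07, "npv": 100.00, "fpr": 0.01, "fnr": 22.22}},
    "Total":{"positive": 598, "tp": 328, "fp": 260, "tn": 59853, "fn": 2, "printed": {"sensitivity": 99.39,  "specificity": 99.57, "ppv": 55.78, "npv": 100.00, "fpr": 0.43, "fnr": 0.76}}
  },
  "positive_distribution": {
    "SCAs": 334, "RAAs": 122, "CNVs": 67, "T21": 41, "T13": 24, "T18": 10
  },
  "raa": {
    "n_positive": 122,
    "n_true_positive": 39,
    "tp_chr16": 13,
    "n_monosomy_positive": 3,
    "n_combined_double": 3,
    "prenatal_diagnosis_rate_pct": 95.90
  },
  "outcomes": {
    "common_trisomy": {
      "TP":     {"n": 47,  "termination": 43,  "stillbirth": 4, "childbirth": 0},
      "FP":     {"n": 24,  "termination": 1,   "stillbirth": 0, "childbirth": 23},
      "Refuse": {"n": 4,   "termination": 3,   "stillbirth": 1, "childbirth": 0}
    },
    "SCA": {
      "TP":     {"n": 187, "termination": 146, "stillbirth": 0, "childbirth": 41},
      "FP":     {"n": 132, "termination": 1,   "stillbirth": 0, "childbirth": 131},
      "Refuse": {"n": 15,  "termination": 3,   "stillbirth": 0, "childbirth": 12}
    },
    "RAA": {
      "TP":     {"n": 39,  "termination": 31,  "stillbirth": 0, "childbirth": 8},
      "FP":     {"n": 78,  "termination": 0,   "stillbirth": 1, "childbirth": 77},
      "Refuse": {"n": 5,   "termination": 1,   "stillbirth": 0, "childbirth": 4}
    },
    "CNV": {
      "TP":     {"n": 46,  "termination": 31,  "stillbirth": 0, "childbirth": 15},
      "FP":     {"n": 19,  "termination": 0,   "stillbirth": 0, "childbirth": 19},
      "Refuse": {"n": 2,   "termination": 1,   "stillbirth": 0, "childbirth": 1}
    },
    "total": {"n": 598, "termination": 261, "stillbirth": 6, "childbirth": 331}
  },
  "fetal_fraction": {
    "band_5_16_positive_pct": 87.46,
    "band_5_16_true_positive_pct": 91.85,
    "negative_range_pct": [3.57, 30.74],
    "overall_range_pct": [3.57, 38.06]
  }
}
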