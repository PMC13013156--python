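{
  "version": "1.0",
  "description": "Published inner tolerance limits and Equivalent-Score cut-offs on adjusted scores (higher is worse for every score). ES 0 iff adjusted > es0 (the outer-limit cut-off); ES k iff adjusted > es_k cut-off and <= the previous one; ES 4 iff adjusted <= es3 (the median).",
  "bands": {
    "T4":    {"itl": 78.36, "es0": 86.20, "es1": 67.64, "es2": 59.92, "es3": 55.13},
    "E4":    {"itl": 5.39,  "es0": 6.73,  "es1": 3.28,  "es2": 1.73,  "es3": 1.07},
    "T3":    {"itl": 39.20, "es0": 48.03, "es1": 31.74, "es2": 28.54, "es3": 25.76},
    "E3":    {"itl": 0.78,  "es0": 1.78,  "es1": 0.17,  "es2": 0.10,  "es3": 0.03},
    "T2":    {"itl": 37.41, "es0": 44.98, "es1": 33.30, "es2": 30.32, "es3": 27.94},
    "E2":    {"itl": 5.79,  "es0": 6.08,  "es1": 4.27,  "es2": 2.30,  "es3": 0.16},
    "T1":    {"itl": 30.29, "es0": 32.85, "es1": 32.85, "es2": 27.18, "es3": 25.05},
    "T4-T3": {"itl": 54.01, "es0": 57.05, "es1": 42.02, "es2": 35.34, "es3": 30.21},
    "E4-E3": {"itl": 5.26,  "es0": 6.46,  "es1": 3.22,  "es2": 1.57,  "es3": 0.82},
    "T4-T2": {"itl": 50.09, "es0": 54.50, "es1": 38.96, "es2": 33.26, "es3": 28.36},
    "E4-E2": {"itl": 5.42,  "es0": 6.70,  "es1": 3.18,  "es2": 1.70,  "es3": 1.07},
    "T3-T1": {"itl": 11.11, "es0": 17.87, "es1": 5.16,  "es2": 3.52,  "es3": 2.18}
  }
}
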