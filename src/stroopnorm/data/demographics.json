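{
  "version": "1.0",
  "description": "Normative-sample stratum table: counts of (male, female) participants per age band x education band. Totals: 452 participants, 200 male / 252 female.",
  "age_bands": [[20, 24], [25, 29], [30, 34], [35, 39], [40, 44], [45, 49], [50, 54], [55, 59], [60, 64], [65, 69], [70, 74], [75, 79], [80, 84], [85, 90]],
  "education_bands": [[0, 4], [5, 8], [9, 13], [14, 19]],
  "counts": {
    "20-24": {"0-4": [0, 0], "5-8": [0, 0], "9-13": [0, 0], "14-19": [8, 6]},
    "25-29": {"0-4": [0, 0], "5-8": [0, 0], "9-13": [4, 2], "14-19": [5, 11]},
    "30-34": {"0-4": [0, 0], "5-8": [0, 0], "9-13": [5, 3], "14-19": [7, 8]},
    "35-39": {"0-4": [0, 0], "5-8": [0, 0], "9-13": [4, 7], "14-19": [9, 9]},
    "40-44": {"0-4": [0, 1], "5-8": [1, 3], "9-13": [5, 4], "14-19": [10, 16]},
    "45-49": {"0-4": [0, 0], "5-8": [2, 3], "9-13": [7, 7], "14-19": [7, 9]},
    "50-54": {"0-4": [0, 0], "5-8": [1, 9], "9-13": [5, 6], "14-19": [15, 17]},
    "55-59": {"0-4": [0, 1], "5-8": [8, 6], "9-13": [7, 6], "14-19": [9, 10]},
    "60-64": {"0-4": [0, 1], "5-8": [4, 6], "9-13": [5, 7], "14-19": [5, 9]},
    "65-69": {"0-4": [2, 1], "5-8": [7, 7], "9-13": [4, 6], "14-19": [5, 6]},
    "70-74": {"0-4": [1, 3], "5-8": [5, 6], "9-13": [5, 7], "14-19": [10, 9]},
    "75-79": {"0-4": [1, 3], "5-8": [4, 9], "9-13": [2, 2], "14-19": [5, 5]},
    "80-84": {"0-4": [2, 1], "5-8": [1, 7], "9-13": [4, 2], "14-19": [3, 3]},
    "85-90": {"0-4": [0, 3], "5-8": [2, 2], "9-13": [1, 1], "14-19": [3, 2]}
  }
}
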