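{
  "version": "1.0",
  "description": "Published band-midpoint correction grids (additive corrections, 2 d.p.). Rows are education bands (null for age-only scores), columns the 14 age bands.",
  "age_bands": [[20, 24], [25, 29], [30, 34], [35, 39], [40, 44], [45, 49], [50, 54], [55, 59], [60, 64], [65, 69], [70, 74], [75, 79], [80, 84], [85, 90]],
  "education_bands": [[0, 4], [5, 8], [9, 13], [14, 19]],
  "grids": {
    "T4": [
      [-6.82, -7.51, -8.50, -9.86, -11.63, -13.89, -16.67, -20.05, -24.08, -28.81, -34.31, -40.62, -47.81, -56.80],
      [6.60, 5.92, 4.92, 3.57, 1.79, -0.46, -3.25, -6.63, -10.66, -15.39, -20.89, -27.20, -34.39, -43.37],
      [12.59, 11.91, 10.92, 9.56, 7.78, 5.53, 2.74, -0.64, -4.67, -9.40, -14.89, -21.21, -28.39, -37.38],
      [17.21, 16.52, 15.53, 14.18, 12.40, 10.15, 7.36, 3.98, -0.05, -4.78, -10.28, -16.59, -23.78, -32.76]
    ],
    "E4": [
      [-0.80, -0.85, -0.92, -1.02, -1.15, -1.31, -1.51, -1.76, -2.05, -2.40, -2.79, -3.25, -3.77, -4.43],
      [0.39, 0.34, 0.27, 0.17, 0.04, -0.12, -0.33, -0.57, -0.86, -1.21, -1.60, -2.06, -2.58, -3.24],
      [0.92, 0.87, 0.80, 0.70, 0.57, 0.41, 0.21, -0.04, -0.33, -0.67, -1.07, -1.53, -2.05, -2.71],
      [1.33, 1.28, 1.21, 1.11, 0.98, 0.82, 0.62, 0.37, 0.08, -0.27, -0.66, -1.12, -1.64, -2.30]
    ],
    "T3": [
      [-4.25, -4.56, -5.02, -5.64, -6.46, -7.49, -8.77, -10.32, -12.17, -14.35, -16.87, -19.77, -23.07, -27.19],
      [2.70, 2.39, 1.93, 1.31, 0.50, -0.54, -1.82, -3.37, -5.22, -7.39, -9.92, -12.81, -16.11, -20.24],
      [5.81, 5.49, 5.04, 4.41, 3.60, 2.56, 1.28, -0.27, -2.12, -4.29, -6.81, -9.71, -13.01, -17.14],
      [8.20, 7.88, 7.43, 6.81, 5.99, 4.96, 3.68, 2.12, 0.28, -1.90, -4.42, -7.32, -10.62, -14.74]
    ],
    "E3": [
      [0.19, 0.18, 0.17, 0.14, 0.12, 0.08, 0.04, -0.02, -0.08, -0.16, -0.24, -0.34, -0.46, -0.60]
    ],
    "T2": [
      [-2.13, -2.43, -2.87, -3.46, -4.25, -5.24, -6.47, -7.96, -9.73, -11.82, -14.24, -17.02, -20.19, -24.15],
      [3.17, 2.86, 2.43, 1.83, 1.05, 0.05, -1.18, -2.66, -4.44, -6.52, -8.95, -11.73, -14.89, -18.85],
      [5.53, 5.23, 4.79, 4.19, 3.41, 2.42, 1.19, -0.30, -2.08, -4.16, -6.58, -9.36, -12.53, -16.49],
      [7.35, 7.05, 6.61, 6.01, 5.23, 4.24, 3.01, 1.52, -0.26, -2.34, -4.76, -7.54, -10.71, -14.67]
    ],
    "E2": [
      [6.14, 5.79, 5.29, 4.61, 3.71, 2.56, 1.15, -0.56, -2.60, -5.00, -7.78, -10.98, -14.62, -19.17]
    ],
    "T1": [
      [-2.85, -3.00, -3.22, -3.53, -3.93, -4.44, -5.07, -5.83, -6.74, -7.81, -9.05, -10.47, -12.09, -14.12],
      [1.11, 0.95, 0.73, 0.42, 0.02, -0.49, -1.12, -1.88, -2.79, -3.85, -5.09, -6.52, -8.14, -10.17],
      [2.87, 2.72, 2.49, 2.19, 1.79, 1.28, 0.65, -0.11, -1.02, -2.09, -3.33, -4.75, -6.38, -8.40],
      [4.23, 4.08, 3.85, 3.55, 3.15, 2.64, 2.01, 1.25, 0.34, -0.73, -1.97, -3.39, -5.02, -7.04]
    ],
    "T4-T3": [
      [8.38, 6.22, 4.05, 1.89, -0.28, -2.44, -4.61, -6.77, -8.94, -11.10, -13.27, -15.43, -17.60, -19.98],
      [12.16, 10.00, 7.83, 5.67, 3.50, 1.34, -0.83, -2.99, -5.16, -7.32, -9.49, -11.65, -13.82, -16.20],
      [14.72, 12.55, 10.39, 8.22, 6.06, 3.89, 1.73, -0.44, -2.60, -4.77, -6.93, -9.10, -11.26, -13.65],
      [17.20, 15.03, 12.87, 10.70, 8.54, 6.37, 4.21, 2.04, -0.12, -2.29, -4.45, -6.62, -8.78, -11.16]
    ],
    "E4-E3": [
      [-2.25, -2.29, -2.35, -2.42, -2.52, -2.65, -2.81, -3.00, -3.23, -3.50, -3.81, -4.17, -4.58, -5.09],
      [0.26, 0.22, 0.16, 0.09, -0.01, -0.14, -0.30, -0.49, -0.72, -0.99, -1.30, -1.66, -2.07, -2.58],
      [0.72, 0.68, 0.62, 0.54, 0.44, 0.31, 0.16, -0.04, -0.26, -0.53, -0.84, -1.20, -1.61, -2.12],
      [0.94, 0.90, 0.84, 0.76, 0.66, 0.53, 0.38, 0.18, -0.04, -0.31, -0.62, -0.98, -1.39, -1.90]
    ],
    "T4-T2": [
      [4.26, 2.05, -0.16, -2.36, -4.57, -6.78, -8.99, -11.20, -13.41, -15.61, -17.82, -20.03, -22.24, -24.67],
      [11.71, 9.51, 7.30, 5.09, 2.88, 0.67, -1.54, -3.74, -5.95, -8.16, -10.37, -12.58, -14.79, -17.22],
      [15.04, 12.83, 10.62, 8.42, 6.21, 4.00, 1.79, -0.42, -2.63, -4.83, -7.04, -9.25, -11.46, -13.89],
      [17.60, 15.40, 13.19, 10.98, 8.77, 6.56, 4.35, 2.15, -0.06, -2.27, -4.48, -6.69, -8.90, -11.33]
    ],
    "E4-E2": [
      [-0.55, -0.68, -0.82, -0.97, -1.14, -1.32, -1.51, -1.73, -1.98, -2.26, -2.59, -2.98, -3.47, -4.19],
      [0.63, 0.50, 0.36, 0.20, 0.04, -0.14, -0.34, -0.56, -0.80, -1.08, -1.41, -1.80, -2.29, -3.01],
      [1.15, 1.02, 0.88, 0.73, 0.56, 0.39, 0.19, -0.03, -0.28, -0.56, -0.88, -1.28, -1.76, -2.49],
      [1.56, 1.43, 1.29, 1.13, 0.97, 0.79, 0.59, 0.37, 0.13, -0.15, -0.48, -0.87, -1.36, -2.08]
    ],
    "T3-T1": [
      [-4.81, -4.97, -5.19, -5.50, -5.90, -6.40, -7.03, -7.80, -8.70, -9.77, -11.01, -12.44, -14.06, -16.08],
      [1.64, 1.48, 1.26, 0.95, 0.55, 0.04, -0.59, -1.35, -2.26, -3.33, -4.56, -5.99, -7.61, -9.64],
      [2.81, 2.65, 2.43, 2.12, 1.72, 1.21, 0.59, -0.18, -1.09, -2.15, -3.39, -4.82, -6.44, -8.47],
      [3.37, 3.22, 2.99, 2.69, 2.29, 1.78, 1.15, 0.39, -0.52, -1.59, -2.83, -4.25, -5.87, -7.90]
    ]
  }
}
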