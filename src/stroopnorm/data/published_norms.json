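{
  "version": "1.0",
  "description": "Published demographic-correction formulas for the 50-item Stroop test: corrected = raw + correction, correction = -(sum coef*(transform(cov) - centring)). Scores whose published formula does not regenerate the published band-midpoint correction grid are flagged consistent=false; for those the grid-lookup mode reproduces clinical practice.",
  "norms": {
    "T1": {
      "consistent": true,
      "terms": [
        {"covariate": "education", "transform": "ln", "coefficient": -3.3535984, "centring": 2.3589319665131},
        {"covariate": "age", "transform": "cube", "coefficient": 1.71e-05, "centring": 170912.989789193}
      ]
    },
    "T2": {
      "consistent": true,
      "terms": [
        {"covariate": "education", "transform": "ln", "coefficient": -4.4905181, "centring": 2.3589319665131},
        {"covariate": "age", "transform": "cube", "coefficient": 3.34e-05, "centring": 170912.989789193}
      ]
    },
    "T3": {
      "consistent": true,
      "terms": [
        {"covariate": "education", "transform": "ln", "coefficient": -5.8994342, "centring": 2.3589319665131},
        {"covariate": "age", "transform": "cube", "coefficient": 3.48e-05, "centring": 170912.989789193}
      ]
    },
    "T4": {
      "consistent": false,
      "note": "as-published formula does not regenerate the published correction grid, which instead behaves as ln-education + cubic-age",
      "terms": [
        {"covariate": "education", "transform": "sqrt", "coefficient": -8.021699, "centring": 3.16314629759675},
        {"covariate": "age", "transform": "ln_100_minus_age", "coefficient": -30.9378348, "centring": 3.65101496467337}
      ]
    },
    "E2": {
      "consistent": true,
      "terms": [
        {"covariate": "age", "transform": "cube", "coefficient": 3.84e-05, "centring": 170575.099525605}
      ]
    },
    "E3": {
      "consistent": true,
      "terms": [
        {"covariate": "age", "transform": "cube", "coefficient": 1.2e-06, "centring": 170912.989789193}
      ]
    },
    "E4": {
      "consistent": false,
      "note": "as-published formula does not regenerate the published correction grid",
      "terms": [
        {"covariate": "education", "transform": "ln", "coefficient": -1.0398004, "centring": 2.3589319665131},
        {"covariate": "age", "transform": "ln_100_minus_age", "coefficient": -2.2906369, "centring": 3.65101496467337}
      ]
    },
    "T3-T1": {
      "consistent": true,
      "terms": [
        {"covariate": "education", "transform": "reciprocal", "coefficient": 18.6240033, "centring": 0.0945211210280571},
        {"covariate": "age", "transform": "cube", "coefficient": 1.71e-05, "centring": 170912.989789193}
      ]
    },
    "T4-T2": {
      "consistent": true,
      "terms": [
        {"covariate": "education", "transform": "ln", "coefficient": -6.3232321, "centring": 2.3589319665131},
        {"covariate": "age", "transform": "identity", "coefficient": 0.4416765, "centring": 55.4955752}
      ]
    },
    "T4-T3": {
      "consistent": false,
      "note": "published per-year age coefficient (7.1500263) is incompatible with the published grid slope (~0.43/year)",
      "terms": [
        {"covariate": "education", "transform": "sqrt", "coefficient": -0.5593092, "centring": 3.16314629759675},
        {"covariate": "age", "transform": "identity", "coefficient": 7.1500263, "centring": 61.4862637}
      ]
    },
    "E4-E2": {
      "consistent": true,
      "terms": [
        {"covariate": "education", "transform": "ln", "coefficient": -0.9990949, "centring": 2.35842458076661},
        {"covariate": "age", "transform": "ln_100_minus_age", "coefficient": -1.9898895, "centring": 3.79641056233036}
      ]
    },
    "E4-E3": {
      "consistent": false,
      "note": "as-published formula does not regenerate the published correction grid",
      "terms": [
        {"covariate": "education", "transform": "reciprocal", "coefficient": 7.1613468, "centring": 0.0999450851729517},
        {"covariate": "age", "transform": "ln_100_minus_age", "coefficient": -1.703813, "centring": 3.65101496467337}
      ]
    }
  }
}
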