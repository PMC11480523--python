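{
  "porcupine_adult_hfl": {
    "herd": "porcupine",
    "trait": "hfl",
    "age_class": "adult",
    "timescale": "annual",
    "alpha": 45.7,
    "beta": -0.32,
    "sigma": 1.8,
    "beta_ci": {
      "beta": [
        -0.35,
        -0.26
      ]
    },
    "years": [
      1987,
      1998
    ],
    "shape": "trough",
    "start_size": 180000,
    "peak_size": 120000,
    "end_size": 180000,
    "survey_every": 1,
    "rel_error": 0.1,
    "span": 0.4,
    "n_per_year": 40
  },
  "porcupine_adult_mass": {
    "herd": "porcupine",
    "trait": "mass",
    "age_class": "adult",
    "timescale": "annual",
    "alpha": 82.98,
    "beta": 0.72,
    "sigma": 9.94,
    "beta_ci": {
      "beta": [
        0.17,
        0.99
      ]
    },
    "years": [
      1987,
      1998
    ],
    "shape": "trough",
    "start_size": 180000,
    "peak_size": 120000,
    "end_size": 180000,
    "survey_every": 1,
    "rel_error": 0.1,
    "span": 0.4,
    "n_per_year": 40
  },
  "beverly_adult_mass": {
    "herd": "beverly",
    "trait": "mass",
    "age_class": "adult",
    "timescale": "annual",
    "alpha": 69.65,
    "beta": 0.61,
    "sigma": 7.9,
    "beta_ci": {
      "beta": [
        0.4,
        0.92
      ]
    },
    "years": [
      1971,
      1987
    ],
    "shape": "trough",
    "start_size": 210000,
    "end_size": 250000,
    "survey_every": 2,
    "rel_error": 0.32,
    "span": 0.75,
    "n_per_year": 80,
    "peak_year": 1980,
    "peak_size": 110000,
    "trait_years": [
      1980,
      1987
    ]
  },
  "beverly_adult_fat_seasonal": {
    "herd": "beverly",
    "trait": "fat",
    "age_class": "adult",
    "timescale": "seasonal",
    "sigma": 2.31,
    "season_effects": {
      "early_winter": [
        11.28,
        0.0
      ],
      "late_winter": [
        9.78,
        0.15
      ]
    },
    "beta_ci": {
      "beta[early_winter]": [
        -0.11,
        0.1
      ],
      "beta[late_winter]": [
        0.09,
        0.24
      ]
    },
    "years": [
      1971,
      1987
    ],
    "shape": "trough",
    "start_size": 210000,
    "end_size": 250000,
    "survey_every": 2,
    "rel_error": 0.32,
    "span": 0.75,
    "n_per_year": 60,
    "peak_year": 1980,
    "peak_size": 110000,
    "trait_years": [
      1980,
      1987
    ]
  },
  "raf_newborn_hfl": {
    "herd": "raf",
    "trait": "hfl",
    "age_class": "newborn",
    "timescale": "annual",
    "alpha": 34.76,
    "beta": -0.03,
    "sigma": 1.89,
    "beta_ci": {
      "beta": [
        -0.05,
        -0.02
      ]
    },
    "years": [
      1988,
      2000
    ],
    "shape": "growth",
    "start_size": 300000,
    "end_size": 600000,
    "survey_every": 1,
    "rel_error": 0.15,
    "span": 0.75,
    "n_per_year": 20
  },
  "rg_adult_mass_phase": {
    "herd": "rg",
    "trait": "mass",
    "age_class": "adult",
    "timescale": "annual",
    "phase_interaction": true,
    "alpha": 93.18,
    "sigma": 10.18,
    "phase_betas": {
      "growth": -0.12,
      "decline": -0.21
    },
    "beta_ci": {
      "beta[growth]": [
        -0.18,
        -0.06
      ],
      "beta[decline]": [
        -0.32,
        -0.09
      ]
    },
    "years": [
      1984,
      1998
    ],
    "shape": "peak",
    "peak_year": 1991,
    "start_size": 300000,
    "peak_size": 800000,
    "end_size": 350000,
    "survey_every": 1,
    "rel_error": 0.15,
    "span": 0.75,
    "n_per_year": 40
  },
  "rg_yearling_mass": {
    "herd": "rg",
    "trait": "mass",
    "age_class": "yearling",
    "timescale": "annual",
    "alpha": 45.43,
    "beta": -0.06,
    "sigma": 5.31,
    "beta_ci": {
      "beta": [
        -0.1,
        -0.02
      ]
    },
    "years": [
      1992,
      2008
    ],
    "shape": "decline",
    "start_size": 800000,
    "end_size": 100000,
    "survey_every": 1,
    "rel_error": 0.15,
    "span": 0.75,
    "n_per_year": 10
  },
  "beverly_adult_hfl_phase": {
    "herd": "beverly",
    "trait": "hfl",
    "age_class": "adult",
    "timescale": "annual",
    "phase_interaction": true,
    "alpha": 36.61,
    "sigma": 1.32,
    "phase_betas": {
      "decline": 0.02,
      "growth": 0.04
    },
    "beta_ci": {
      "beta[growth]": [
        0.02,
        0.07
      ],
      "beta[decline]": [
        -0.01,
        0.05
      ]
    },
    "years": [
      1971,
      1994
    ],
    "shape": "trough",
    "peak_year": 1980,
    "start_size": 210000,
    "peak_size": 110000,
    "end_size": 276000,
    "survey_every": 2,
    "rel_error": 0.32,
    "span": 0.75,
    "n_per_year": 40,
    "trait_years": [
      1971,
      1986
    ]
  }
}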