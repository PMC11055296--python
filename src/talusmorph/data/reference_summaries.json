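{
  "description": "Published reference cohort summaries for the talar trochlea (91 talus models from 61 adult specimens): per-region radius-of-curvature summaries and cylinder-fit radius summaries, with the statistics printed alongside them. Used by the check-reference mode to verify that the summary-statistics layer reproduces the printed values.",
  "regions": {
    "AM": {"n": 91, "mean": 15.97, "sd": 3.08, "min": 10.19, "max": 25.51},
    "AL": {"n": 91, "mean": 22.06, "sd": 3.94, "min": 14.78, "max": 38.74},
    "PL": {"n": 91, "mean": 27.95, "sd": 12.08, "min": 16.07, "max": 89.98},
    "PM": {"n": 91, "mean": 34.17, "sd": 16.22, "min": 14.4, "max": 91.41},
    "MP": {"n": 91, "mean": 22.44, "sd": 5.05, "min": 15.34, "max": 52.98},
    "MA": {"n": 91, "mean": 16.97, "sd": 3.09, "min": 10.46, "max": 27.87}
  },
  "fitted_radius": {
    "overall": {"n": 91, "mean": 20.52, "sd": 1.95, "min": 15.18, "max": 25.3},
    "male": {"n": 37, "mean": 21.9, "sd": 1.97},
    "female": {"n": 54, "mean": 19.57, "sd": 1.26},
    "right": {"n": 41, "mean": 20.69, "sd": 2.0},
    "left": {"n": 50, "mean": 20.37, "sd": 1.92}
  },
  "printed_statistics": {
    "anova_regions_F": 54.905,
    "fitted_t_male_vs_female": 6.894,
    "fitted_t_right_vs_left": 0.783,
    "pooled_fitted_mean": 20.52,
    "pooled_fitted_sd": 1.95,
    "corr_age_fitted_r": -0.015
  },
  "region_ordering": ["PM", "PL", "MP", "AL", "MA", "AM"],
  "cohort": {
    "n_specimens": 61,
    "n_tali": 91,
    "n_male": 28,
    "n_female": 33,
    "n_male_tali": 37,
    "n_female_tali": 54,
    "n_right": 41,
    "n_left": 50,
    "n_bilateral": 30,
    "mean_age": 37.43,
    "median_age": 38,
    "age_range": [14, 69]
  }
}
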