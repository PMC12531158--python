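{
  "description": "Spatial econometric estimates for the provincial hospital financial-sustainability index (403 observations, 31 provinces, 2010-2022). Each covariate entry holds [estimate, standard_error] per column.",
  "covariates": {
    "fiscal_ratio": {
      "label": "Government fiscal medical expenditure ratio",
      "OLS": [0.298, 0.042], "SAR": [0.275, 0.038], "SEM": [0.281, 0.041], "SDM": [0.312, 0.045],
      "direct": [0.312, 0.045], "indirect": [0.089, 0.039], "total": [0.401, 0.052]
    },
    "insurance_coverage": {
      "label": "Medical insurance coverage rate",
      "OLS": [0.187, 0.035], "SAR": [0.165, 0.032], "SEM": [0.172, 0.034], "SDM": [0.194, 0.037],
      "direct": [0.194, 0.037], "indirect": [0.067, 0.031], "total": [0.261, 0.043]
    },
    "drg_intensity": {
      "label": "DRG implementation intensity",
      "OLS": [0.145, 0.058], "SAR": [0.138, 0.055], "SEM": [0.142, 0.057], "SDM": [0.156, 0.061],
      "direct": [0.156, 0.061], "indirect": [0.041, 0.023], "total": [0.197, 0.068]
    },
    "log_gdp_pc": {
      "label": "Per capita GDP (log)",
      "OLS": [0.234, 0.028], "SAR": [0.218, 0.026], "SEM": [0.225, 0.027], "SDM": [0.247, 0.030],
      "direct": [0.247, 0.030], "indirect": [0.073, 0.029], "total": [0.320, 0.039]
    },
    "urbanization": {
      "label": "Urbanization rate",
      "OLS": [0.163, 0.031], "SAR": [0.151, 0.029], "SEM": [0.157, 0.030], "SDM": [0.174, 0.033],
      "direct": [0.174, 0.033], "indirect": [0.052, 0.027], "total": [0.226, 0.041]
    },
    "aging": {
      "label": "Aging degree",
      "OLS": [-0.089, 0.036], "SAR": [-0.082, 0.033], "SEM": [-0.085, 0.035], "SDM": [-0.095, 0.038],
      "direct": [-0.095, 0.038], "indirect": [-0.028, 0.015], "total": [-0.123, 0.042]
    },
    "log_density": {
      "label": "Population density (log)",
      "OLS": [0.067, 0.035], "SAR": [0.063, 0.032], "SEM": [0.065, 0.034], "SDM": [0.071, 0.037],
      "direct": [0.071, 0.037], "indirect": [0.019, 0.016], "total": [0.090, 0.041]
    },
    "doctors_per_1000": {
      "label": "Doctors per thousand population",
      "OLS": [0.128, 0.025], "SAR": [0.119, 0.023], "SEM": [0.123, 0.024], "SDM": [0.136, 0.027],
      "direct": [0.136, 0.027], "indirect": [0.043, 0.022], "total": [0.179, 0.032]
    },
    "demand_intensity": {
      "label": "Medical demand intensity",
      "OLS": [-0.076, 0.032], "SAR": [-0.071, 0.029], "SEM": [-0.073, 0.031], "SDM": [-0.081, 0.034],
      "direct": [-0.081, 0.034], "indirect": [-0.021, 0.014], "total": [-0.102, 0.038]
    }
  },
  "spatial_parameters": {
    "rho_SAR": [0.347, 0.058],
    "rho_SDM": [0.289, 0.062],
    "lambda_SEM": [0.412, 0.071]
  },
  "diagnostics": {
    "r_squared": {"OLS": 0.734, "SAR": 0.758, "SEM": 0.751, "SDM": 0.769},
    "loglik": {"OLS": 156.34, "SAR": 168.72, "SEM": 164.58, "SDM": 173.95},
    "aic": {"OLS": -288.68, "SAR": -309.44, "SEM": -301.16, "SDM": -317.90},
    "lm_lag": 12.67,
    "lm_error": 9.84
  }
}
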