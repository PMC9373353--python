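{
  "discount_rate": {"family": "fixed", "value": 0.015},
  "wtp": {"family": "fixed", "value": 50000},
  "transition": {
    "GII_GIII": {"family": "beta", "alpha": 7, "beta": 84, "base": 0.08},
    "GIII_GIV": {"family": "beta", "alpha": 2, "beta": 39, "base": 0.05}
  },
  "mortality_rr": {
    "GII": {"family": "lognormal_ci", "ci_lower": 1.135, "ci_upper": 1.778, "base": 1.44},
    "GIII": {"family": "lognormal_ci", "ci_lower": 1.495, "ci_upper": 2.569, "base": 2.04},
    "GIV": {"family": "lognormal_ci", "ci_lower": 1.496, "ci_upper": 3.921, "base": 4.24}
  },
  "hosp_death_hr": {
    "GII": {"family": "lognormal_ci", "ci_lower": 1.260, "ci_upper": 1.757, "base": 1.5},
    "GIII_GIV": {"family": "lognormal_ci", "ci_lower": 2.066, "ci_upper": 3.214, "base": 2.7}
  },
  "arms": {
    "UC": {
      "GII": {
        "p_exacerbation": {"family": "beta", "alpha": 38, "beta": 6, "base": 0.86},
        "p_urgent": {"family": "beta", "alpha": 34, "beta": 4, "base": 0.89},
        "p_er": {"family": "beta", "alpha": 17, "beta": 21, "base": 0.45},
        "p_hosp": {"family": "beta", "alpha": 7, "beta": 31, "base": 0.18},
        "n_urgent": {"family": "lognormal_ci", "ci_lower": 2.074, "ci_upper": 3.185, "base": 2.684},
        "n_er": {"family": "lognormal_ci", "ci_lower": 0.326, "ci_upper": 0.683, "base": 0.474},
        "n_hosp": {"family": "lognormal_ci", "ci_lower": 0.123, "ci_upper": 0.554, "base": 0.263},
        "utility": {"family": "resample", "min": 0.377, "median": 0.733, "max": 0.922, "mean": 0.711, "n": 44}
      },
      "GIII": {
        "p_exacerbation": {"family": "beta", "alpha": 16, "beta": 6, "base": 0.73},
        "p_urgent": {"family": "beta", "alpha": 12, "beta": 4, "base": 0.75},
        "p_er": {"family": "beta", "alpha": 8, "beta": 8, "base": 0.50},
        "p_hosp": {"family": "beta", "alpha": 4, "beta": 12, "base": 0.25},
        "n_urgent": {"family": "lognormal_ci", "ci_lower": 1.178, "ci_upper": 2.964, "base": 2.124},
        "n_er": {"family": "lognormal_ci", "ci_lower": 0.403, "ci_upper": 1.322, "base": 0.75},
        "n_hosp": {"family": "lognormal_ci", "ci_lower": 0.166, "ci_upper": 1.095, "base": 0.438},
        "utility": {"family": "resample", "min": 0.472, "median": 0.673, "max": 0.959, "mean": 0.687, "n": 22}
      },
      "GIV": {
        "p_exacerbation": {"family": "beta", "alpha": 6, "beta": 1, "base": 0.86},
        "p_urgent": {"family": "beta", "alpha": 6, "beta": 0.1, "base": 0.98},
        "p_er": {"family": "beta", "alpha": 3, "beta": 3, "base": 0.50},
        "p_hosp": {"family": "beta", "alpha": 2, "beta": 4, "base": 0.33},
        "n_urgent": {"family": "lognormal_ci", "ci_lower": 0.603, "ci_upper": 2.628, "base": 3.833},
        "n_er": {"family": "lognormal_ci", "ci_lower": 0.262, "ci_upper": 2.112, "base": 0.833},
        "n_hosp": {"family": "lognormal_ci", "ci_lower": 0.105, "ci_upper": 1.016, "base": 0.333},
        "utility": {"family": "resample", "min": 0.544, "median": 0.726, "max": 0.889, "mean": 0.708, "n": 7}
      }
    },
    "IDM": {
      "GII": {
        "p_exacerbation": {"family": "beta", "alpha": 12, "beta": 35, "base": 0.26},
        "p_urgent": {"family": "beta", "alpha": 9, "beta": 3, "base": 0.75},
        "p_er": {"family": "beta", "alpha": 5, "beta": 7, "base": 0.42},
        "p_hosp": {"family": "beta", "alpha": 2, "beta": 10, "base": 0.17},
        "n_urgent": {"family": "lognormal_ci", "ci_lower": 1.069, "ci_upper": 2.324, "base": 1.667},
        "n_er": {"family": "lognormal_ci", "ci_lower": 0.209, "ci_upper": 0.812, "base": 0.417},
        "n_hosp": {"family": "lognormal_ci", "ci_lower": 0.098, "ci_upper": 1.577, "base": 0.417},
        "utility": {"family": "resample", "min": 0.566, "median": 0.836, "max": 0.978, "mean": 0.817, "n": 47}
      },
      "GIII": {
        "p_exacerbation": {"family": "beta", "alpha": 9, "beta": 10, "base": 0.47},
        "p_urgent": {"family": "beta", "alpha": 4, "beta": 5, "base": 0.44},
        "p_er": {"family": "beta", "alpha": 1, "beta": 8, "base": 0.11},
        "p_hosp": {"family": "beta", "alpha": 2, "beta": 7, "base": 0.22},
        "n_urgent": {"family": "lognormal_ci", "ci_lower": 0.250, "ci_upper": 1.592, "base": 0.667},
        "n_er": {"family": "lognormal_ci", "ci_lower": 0.042, "ci_upper": 1.108, "base": 0.222},
        "n_hosp": {"family": "lognormal_ci", "ci_lower": 0.068, "ci_upper": 0.716, "base": 0.222},
        "utility": {"family": "resample", "min": 0.548, "median": 0.759, "max": 0.978, "mean": 0.798, "n": 19}
      },
      "GIV": {
        "p_exacerbation": {"family": "beta", "alpha": 2, "beta": 2, "base": 0.50},
        "p_urgent": {"family": "beta", "alpha": 2, "beta": 0.1, "base": 0.95},
        "p_er": {"family": "beta", "alpha": 1, "beta": 1, "base": 0.50},
        "p_hosp": {"family": "beta", "alpha": 1, "beta": 1, "base": 0.50},
        "n_urgent": {"family": "lognormal_ci", "ci_lower": 0.701, "ci_upper": 2.501, "base": 1.5},
        "n_er": {"family": "lognormal_ci", "ci_lower": 0.086, "ci_upper": 2.256, "base": 0.5},
        "n_hosp": {"family": "lognormal_ci", "ci_lower": 0.086, "ci_upper": 2.256, "base": 0.5},
        "utility": {"family": "resample", "min": 0.540, "median": 0.771, "max": 0.801, "mean": 0.720, "n": 4}
      }
    }
  },
  "unit_costs": {
    "urgent": {
      "physician": {"family": "gamma", "shape": 10892.910, "scale": 0.00697, "base": 75.93},
      "lab": {"family": "gamma", "shape": 107.360, "scale": 0.186, "base": 19.62},
      "transport": {"family": "gamma", "shape": 61.975, "scale": 0.462, "base": 28.63},
      "medication": {"family": "gamma", "shape": 673.687, "scale": 0.048, "base": 32.36}
    },
    "er": {
      "visit": {"family": "fixed", "value": 313.38},
      "transport": {"family": "gamma", "shape": 40.930, "scale": 7.329, "base": 299.98},
      "medication": {"family": "gamma", "shape": 80.414, "scale": 0.325, "base": 26.14}
    },
    "hosp": {
      "stay": {"family": "gamma", "shape": 63.791, "scale": 137.760, "base": 8787.93},
      "lab": {"family": "gamma", "shape": 309.379, "scale": 5.966, "base": 1845.86},
      "transport": {"family": "gamma", "shape": 24.237, "scale": 6.420, "base": 155.59}
    }
  },
  "intervention": {
    "medical_program_director": {"family": "gamma", "shape": 25, "scale": 1.867, "base": 46.67},
    "program_coordinator": {"family": "gamma", "shape": 25, "scale": 3.2, "base": 80.00},
    "cre": {"family": "gamma", "shape": 25, "scale": 8.64, "base": 216.00},
    "spirometry": {"family": "gamma", "shape": 25, "scale": 0.4, "base": 10.00},
    "computer": {"family": "gamma", "shape": 25, "scale": 0.096, "base": 2.40},
    "spirometry_filters": {"family": "fixed", "value": 5.25}
  }
}
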