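{
  "area_deformation": {
    "model_tag": "area_deformation",
    "s0": 104.32,
    "a": 3.078,
    "b": 6.910,
    "c": 21.456,
    "ci": {
      "s0": [104.06, 104.47],
      "a": [3.068, 3.083],
      "b": [6.819, 6.980],
      "c": [21.352, 21.726]
    },
    "meta": {
      "sigma": 0.1,
      "isovalue": 1.0,
      "grid_spacing": 0.075,
      "n_bins": 64,
      "spherical_threshold": 0.99,
      "log_base": "e",
      "calibration": "published fit to 1942 experimental gas-phase entropies, 95% bootstrap CIs",
      "fit_rmse_jmolk": 21.326,
      "fit_r2": 0.975,
      "fit_mape_percent": 3.94
    }
  },
  "area_only": {
    "model_tag": "area_only",
    "s0": 118.84,
    "a": 1.948,
    "b": 0.0,
    "c": 0.0,
    "ci": {
      "s0": [118.62, 119.23],
      "a": [1.945, 1.959]
    },
    "meta": {
      "sigma": 0.1,
      "isovalue": 1.0,
      "grid_spacing": 0.075,
      "n_bins": 64,
      "spherical_threshold": 0.99,
      "log_base": "e",
      "calibration": "published fit to 1942 experimental gas-phase entropies, 95% bootstrap CIs",
      "fit_rmse_jmolk": 27.977,
      "fit_r2": 0.957,
      "fit_mape_percent": 5.42
    }
  }
}
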