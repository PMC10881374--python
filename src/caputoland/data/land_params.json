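{
  "description": "Human Land-model parameter set for skinned-cell quick stretch simulations, per-second units.",
  "params": {
    "k_uw": 182.0,
    "k_ws": 12.0,
    "r_s": 0.25,
    "r_w": 0.5,
    "phi": 2.23,
    "A_eff": 25.0,
    "gamma_s_scale": 8.5,
    "gamma_w_scale": 615.0,
    "k_TRPN": 100.0,
    "n_TRPN": 2.0,
    "Ca_T50_ref": 0.805,
    "beta_1": -2.4,
    "TRPN_50": 0.35,
    "n_Tm": 2.2,
    "k_u": 1000.0,
    "T_ref": 120.0,
    "beta_0": 2.3,
    "Ca_i": 1.2,
    "lambda_0": 1.1,
    "lambda_cap": 1.2,
    "lambda_min": 0.8,
    "lambda_max": 1.2,
    "catrpn_floor": 1e-08
  },
  "units": {
    "k_uw": "1/s",
    "k_ws": "1/s",
    "r_s": "dimensionless",
    "r_w": "dimensionless",
    "phi": "dimensionless",
    "A_eff": "dimensionless",
    "gamma_s_scale": "1/s",
    "gamma_w_scale": "1/s",
    "k_TRPN": "1/s",
    "n_TRPN": "dimensionless",
    "Ca_T50_ref": "uM",
    "beta_1": "dimensionless",
    "TRPN_50": "dimensionless",
    "n_Tm": "dimensionless",
    "k_u": "1/s",
    "T_ref": "kPa",
    "beta_0": "dimensionless",
    "Ca_i": "uM",
    "lambda_0": "dimensionless",
    "lambda_cap": "dimensionless",
    "lambda_min": "dimensionless",
    "lambda_max": "dimensionless",
    "catrpn_floor": "dimensionless"
  }
}
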