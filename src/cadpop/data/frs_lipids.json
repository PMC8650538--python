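{
  "name": "frs_lipids",
  "description": "Sex-stratified general cardiovascular disease 10-year risk (lipid model): published Cox proportional-hazards coefficients on ln-transformed age, total cholesterol (mg/dL), HDL cholesterol (mg/dL) and systolic blood pressure (mmHg, separate treated/untreated terms), plus binary smoking and diabetes terms, with derivation-cohort baseline survival and mean linear predictor.",
  "sex": {
    "F": {
      "terms": [
        {"variable": "age", "transform": "ln", "beta": 2.32888},
        {"variable": "tc", "transform": "ln", "beta": 1.20904},
        {"variable": "hdl", "transform": "ln", "beta": -0.70833},
        {"variable": "sbp", "transform": "ln", "beta": 2.76157, "condition": {"antihypertensive": false}},
        {"variable": "sbp", "transform": "ln", "beta": 2.82263, "condition": {"antihypertensive": true}},
        {"variable": "smoker", "beta": 0.52873},
        {"variable": "diabetic", "beta": 0.69154}
      ],
      "s0": 0.95012,
      "mean_lp": 26.1931
    },
    "M": {
      "terms": [
        {"variable": "age", "transform": "ln", "beta": 3.06117},
        {"variable": "tc", "transform": "ln", "beta": 1.12370},
        {"variable": "hdl", "transform": "ln", "beta": -0.93263},
        {"variable": "sbp", "transform": "ln", "beta": 1.93303, "condition": {"antihypertensive": false}},
        {"variable": "sbp", "transform": "ln", "beta": 1.99881, "condition": {"antihypertensive": true}},
        {"variable": "smoker", "beta": 0.65451},
        {"variable": "diabetic", "beta": 0.57367}
      ],
      "s0": 0.88936,
      "mean_lp": 23.9802
    }
  }
}
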